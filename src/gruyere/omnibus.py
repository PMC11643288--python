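"""Cauchy p-value combination (ACAT) across rare-variant tests.

The aggregated Cauchy association test maps each p-value through the tangent
transform, averages with nonnegative weights, and maps back:

    T = sum_i w_i tan((0.5 - p_i) pi) / sum_i w_i,   p = 0.5 - arctan(T) / pi.

Because a standard Cauchy average of Cauchy variates is Cauchy, the combined
p-value is uniform under the null even for dependent components, which makes
it a convenient omnibus over correlated gene-level tests.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["acat_combine", "combine_tables"]

_P_CEILING = 1.0 - 1e-15
_TINY = 1e-16


def acat_combine(pvalues: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Combine p-values with the Cauchy (ACAT) statistic.

    Weights default to equal; they must be nonnegative and not all zero.
    ``p == 0`` is undefined (infinite tangent) and raises; ``p == 1`` is
    nudged to ``1 - 1e-15`` with a warning. Very small p-values use the
    standard ``tan((0.5 - p) pi) ~ 1/(p pi)`` approximation, and a very large
    combined statistic returns ``1 / (T pi)``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any():
        raise ValueError("p-values must be strictly positive for ACAT")
    if (p > 1).any():
        raise ValueError("p-values cannot exceed 1")
    if (p == 1).any():
        warnings.warn("p-value of exactly 1 mapped to 1 - 1e-15")
        p = np.minimum(p, _P_CEILING)
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be nonnegative and not all zero")
    terms = np.where(p < _TINY, 1.0 / (p * np.pi), np.tan((0.5 - p) * np.pi))
    T = float(np.sum(w * terms) / np.sum(w))
    if T > 1e15:
        return float(1.0 / (T * np.pi))
    return float(0.5 - np.arctan(T) / np.pi)


def combine_tables(
    gruyere_pvalues: Mapping[str, float] | pd.Series,
    external: pd.DataFrame | None = None,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-gene omnibus combination of this test with external RV tests.

    Parameters
    ----------
    gruyere_pvalues
        Gene -> p-value from the per-gene LRT.
    external
        Long-format table with columns ``gene``, ``method``, ``p``; methods
        missing a gene simply contribute nothing for that gene (logged).
    weights
        Optional method -> weight map (default equal weights).

    Returns
    -------
    DataFrame with columns ``gene``, ``n_methods``, ``p_combined``. A gene
    covered by a single method keeps that method's p-value exactly.
    """
    own = pd.Series(dict(gruyere_pvalues) if not isinstance(gruyere_pvalues, pd.Series)
                    else gruyere_pvalues, name="p")
    tables: dict[str, pd.Series] = {"gruyere": own.dropna()}
    if external is not None and len(external):
        required = {"gene", "method", "p"}
        if not required.issubset(external.columns):
            raise ValueError(f"external table must have columns {sorted(required)}")
        for method, sub in external.groupby("method"):
            tables[str(method)] = sub.set_index("gene")["p"].dropna()
    all_genes = sorted(set().union(*(set(t.index) for t in tables.values())))
    if not all_genes:
        raise ValueError("no genes to combine")
    rows = []
    for gene in all_genes:
        ps, ws = [], []
        for method, t in tables.items():
            if gene in t.index:
                ps.append(float(t.loc[gene]))
                ws.append(1.0 if weights is None else float(weights.get(method, 1.0)))
            else:
                logger.debug("gene %s missing from method %s", gene, method)
        rows.append({"gene": gene, "n_methods": len(ps),
                     "p_combined": acat_combine(ps, ws)})
    return pd.DataFrame(rows)
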