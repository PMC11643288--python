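"""Build the scaled annotation matrix Z from raw per-variant score tables.

Raw functional annotations (conservation, deleteriousness, splicing deltas,
epigenetic signal, ...) arrive as a TSV keyed by variant id. Preprocessing:

1. columns with more than 5% missingness are dropped;
2. residual missing entries are imputed as 0 (least functional);
3. each column is min-max scaled to [0, 1], flipping orientation first when a
   lower raw value means more predicted function;
4. groups of related columns are collapsed to one composite score per
   category - rank-1 non-negative matrix factorization for most categories,
   an element-wise maximum for the sparse SpliceAI splice-disruption deltas,
   and absolute max/min composites for Z-scored sequence-model delta scores.

The result is a p x q matrix Z with entries in [0, 1] whose columns the model
weights with the learned simplex tau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMatrix",
    "drop_sparse_annotations",
    "minmax_scale",
    "nmf_group_score",
    "splice_max",
    "delta_aggregate",
    "build_annotation_matrix",
]


@dataclass
class AnnotationMatrix:
    """Scaled p x q annotation matrix with column labels and group provenance."""

    variant_ids: list[str]
    Z: np.ndarray
    annotation_names: list[str]
    group_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.min() < -1e-12 or self.Z.max() > 1 + 1e-12:
            raise ValueError("annotation matrix entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Z, index=self.variant_ids, columns=self.annotation_names)


def drop_sparse_annotations(raw: pd.DataFrame, missing_max: float = 0.05) -> pd.DataFrame:
    """Drop columns whose missing fraction exceeds ``missing_max``."""
    frac = raw.isna().mean(axis=0)
    keep = frac[frac <= missing_max].index
    dropped = [c for c in raw.columns if c not in set(keep)]
    if dropped:
        logger.info("drop_sparse_annotations: removed %s", dropped)
    if len(keep) == 0:
        raise ValueError("all annotation columns exceed the missingness threshold")
    return raw[list(keep)]


def minmax_scale(column: pd.Series | np.ndarray, higher_is_functional: bool = True) -> np.ndarray:
    """Map a column affinely onto [0, 1], larger = more predicted function.

    If lower raw values indicate more function, the orientation is flipped
    before scaling. A constant column has no usable range and raises.
    """
    x = np.asarray(column, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if not np.isfinite(lo) or not np.isfinite(hi) or hi <= lo:
        raise ValueError("constant or non-finite annotation column; remove it instead")
    if not higher_is_functional:
        x = -x
        lo, hi = -hi, -lo
    return (x - lo) / (hi - lo)


def nmf_group_score(columns: np.ndarray | pd.DataFrame, seed: int = 0) -> np.ndarray:
    """Collapse a category's scaled columns to one score via rank-1 NMF.

    The variant-side factor of the rank-1 factorization, min-max rescaled to
    [0, 1], becomes the category score. Multiplicative updates, 500
    iterations, tolerance 1e-6, deterministic NNDSVDa initialization. A
    single-column category passes through unchanged (rescaled).
    """
    M = np.asarray(columns, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected a 2-D column block")
    if (M < 0).any():
        raise ValueError("NMF inputs must be nonnegative; scale columns first")
    if M.shape[1] == 1:
        return minmax_scale(M[:, 0])
    model = NMF(
        n_components=1, init="nndsvda", solver="mu", max_iter=500, tol=1e-6,
        random_state=seed,
    )
    W = model.fit_transform(M)
    return minmax_scale(W[:, 0])


def splice_max(scores: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Element-wise maximum of the four splice-disruption delta scores.

    SpliceAI's acceptor/donor gain/loss deltas are sparse and weakly
    correlated, so the category score is the per-variant maximum rather than
    an NMF composite. Missing components count as 0 (logged).
    """
    M = np.asarray(scores, dtype=float)
    n_missing = int(np.isnan(M).sum())
    if n_missing:
        logger.info("splice_max: %d missing components treated as 0", n_missing)
        M = np.nan_to_num(M, nan=0.0)
    if ((M < 0) | (M > 1)).any():
        raise ValueError("splice delta scores must lie in [0, 1]")
    return M.max(axis=1)


def delta_aggregate(
    deltas: pd.DataFrame,
    enriched_assays: list[str],
    background_stats: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Composite max/min sequence-model delta scores over enriched assays.

    Each assay column is Z-scored with the supplied background mean/sd (a
    large external cohort's delta-score distribution). Per variant, the
    composite "max" is the magnitude of the most positive Z-score (predicted
    signal gain) and the composite "min" the magnitude of the most negative
    (predicted loss); both are then min-max scaled to [0, 1].

    Parameters
    ----------
    deltas
        Raw delta scores, one column per assay.
    enriched_assays
        Assays enriched in the cell type of interest; only these contribute.
    background_stats
        DataFrame indexed by assay with columns ``mean`` and ``sd``.
    """
    missing = [a for a in enriched_assays if a not in deltas.columns]
    if missing:
        raise ValueError(f"enriched assays absent from delta matrix: {missing}")
    if not enriched_assays:
        raise ValueError("enriched assay list must be nonempty")
    Zs = np.column_stack(
        [
            (deltas[a].to_numpy(float) - background_stats.loc[a, "mean"])
            / background_stats.loc[a, "sd"]
            for a in enriched_assays
        ]
    )
    max_mag = np.abs(Zs.max(axis=1))
    min_mag = np.abs(Zs.min(axis=1))
    return minmax_scale(max_mag), minmax_scale(min_mag)


def build_annotation_matrix(
    raw: pd.DataFrame,
    categories: dict[str, dict],
    missing_max: float = 0.05,
    seed: int = 0,
) -> AnnotationMatrix:
    """Assemble the full Z matrix from a raw table and a category config.

    ``categories`` maps category name to a dict with keys:

    - ``columns``: raw column names in the category;
    - ``method``: ``"nmf"`` (default), ``"max"``, or ``"passthrough"``
      (binary/already-scaled single columns, e.g. a loss-of-function flag);
    - ``direction``: per-column list of booleans, True = higher raw value
      means more function (default all True).

    Raw columns are missingness-filtered, imputed (residual NaN -> 0, the
    least-functional value), oriented, and min-max scaled before grouping.
    """
    raw = drop_sparse_annotations(raw, missing_max)
    cols: list[np.ndarray] = []
    names: list[str] = []
    group_map: dict[str, list[str]] = {}
    for cat, cfg in categories.items():
        use = [c for c in cfg["columns"] if c in raw.columns]
        if not use:
            logger.warning("category %s: no surviving columns, skipped", cat)
            continue
        directions = cfg.get("direction", [True] * len(use))
        method = cfg.get("method", "nmf")
        block = _scaled_block(raw, use, directions)
        if method == "max":
            score = splice_max(block)
        elif method == "passthrough" or len(use) == 1:
            score = block[:, 0]
        else:
            score = nmf_group_score(block, seed=seed)
        cols.append(score)
        names.append(cat)
        group_map[cat] = use
    if not cols:
        raise ValueError("no annotation categories could be built")
    return AnnotationMatrix(
        list(raw.index.astype(str)), np.column_stack(cols), names, group_map
    )


def _scaled_block(
    raw: pd.DataFrame, use: list[str], directions: list[bool]
) -> np.ndarray:
    """Orient, impute residual NaN as least-functional (0), and scale columns."""
    out = []
    for c, d in zip(use, directions):
        x = raw[c].to_numpy(float)
        scaled = np.full_like(x, np.nan)
        obs = ~np.isnan(x)
        if obs.sum() < 2 or np.nanmax(x) <= np.nanmin(x):
            raise ValueError(f"constant or empty annotation column {c!r}")
        scaled[obs] = minmax_scale(x[obs], d)
        scaled[~obs] = 0.0  # least-functional imputation
        out.append(scaled)
    return np.column_stack(out)
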