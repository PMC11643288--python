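"""Prediction-performance metrics: per-gene and cross-gene AUROC/accuracy."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .datatypes import CohortData, GeneVariantSet, GlobalParams
from .model import maf_weight

__all__ = ["MetricReport", "auroc", "accuracy", "average_gene_predictions",
           "predict_gene", "metric_report"]


@dataclass
class MetricReport:
    gene: str  # or "averaged"
    split: str
    auroc: float
    accuracy: float
    n_samples: int


def auroc(y: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney formulation, ties averaged).

    Returns NaN with a warning when only one class is present.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        warnings.warn("AUROC undefined with a single class; returning NaN")
        return np.nan
    return float(roc_auc_score(y, scores))


def accuracy(y: np.ndarray, probs: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of correct calls at a probability threshold (default 0.5)."""
    return float(np.mean((np.asarray(probs) >= threshold) == (np.asarray(y) == 1)))


def average_gene_predictions(prob_matrix: np.ndarray) -> np.ndarray:
    """Arithmetic mean of per-gene predicted probabilities per sample.

    ``prob_matrix`` is ``n x M`` (one column per gene); a single gene is the
    identity.
    """
    P = np.atleast_2d(np.asarray(prob_matrix, dtype=float))
    if P.ndim != 2:
        raise ValueError("expected an n x M probability matrix")
    return P.mean(axis=1)


def predict_gene(
    gvs: GeneVariantSet,
    cohort: CohortData,
    alpha: np.ndarray,
    w_g: float,
    tau: GlobalParams | np.ndarray,
    split: str | None = None,
) -> np.ndarray:
    """Predicted case probabilities mu for one gene's fitted model."""
    t = tau.tau if isinstance(tau, GlobalParams) else np.asarray(tau, dtype=float)
    mask = cohort.mask(split)
    w_j = maf_weight(gvs.maf)
    b = w_j * (t[0] + gvs.Z @ t[1:]) if len(t) == gvs.n_annotations + 1 else w_j * (gvs.Z @ t)
    return expit(cohort.X[mask] @ alpha + w_g * (gvs.G[mask] @ b))


def metric_report(
    y: np.ndarray, probs_by_gene: dict[str, np.ndarray], split: str = "test"
) -> pd.DataFrame:
    """Per-gene plus cross-gene-averaged AUROC/accuracy as a tidy table."""
    rows = []
    for gene, mu in probs_by_gene.items():
        rows.append(vars(MetricReport(gene, split, auroc(y, mu), accuracy(y, mu), len(y))))
    if probs_by_gene:
        avg = average_gene_predictions(np.column_stack(list(probs_by_gene.values())))
        rows.append(vars(MetricReport("averaged", split, auroc(y, avg),
                                      accuracy(y, avg), len(y))))
    return pd.DataFrame(rows)
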