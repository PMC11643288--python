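"""Core in-memory containers shared across the pipeline.

All genotype matrices are dense ``float64`` dosage arrays (samples x variants,
values in [0, 2], fractional after mean imputation). Coordinates follow the VCF
convention (1-based) at the I/O boundary and are converted to half-open 0-based
intervals internally; the conversion lives in the readers, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortData",
    "GenotypeBlock",
    "GeneVariantSet",
    "GeneParams",
    "GlobalParams",
    "JointFitResult",
    "GeneTestResult",
    "SimTruth",
]


@dataclass
class CohortData:
    """Samples with covariates, binary phenotypes, and train/test membership.

    Parameters
    ----------
    sample_ids
        Sample identifiers, length ``n``.
    Y
        Binary phenotype vector (0 = control, 1 = case), or ``None`` before
        phenotypes are attached (e.g. a freshly generated synthetic cohort).
    X
        ``n x c`` covariate matrix; every column lies in [0, 1] after loading.
    covariate_names
        Length-``c`` column labels.
    split
        Optional per-sample ``"train"``/``"test"`` labels.
    ancestry
        Optional categorical ancestry label per sample, used to stratify the
        train/test split.
    """

    sample_ids: list[str]
    Y: np.ndarray | None
    X: np.ndarray
    covariate_names: list[str]
    split: np.ndarray | None = None
    ancestry: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.sample_ids):
            raise ValueError("X must be n x c with n == len(sample_ids)")
        if self.X.shape[1] != len(self.covariate_names):
            raise ValueError("covariate_names length must match X columns")
        if self.X.size and (self.X.min() < -1e-12 or self.X.max() > 1 + 1e-12):
            raise ValueError("covariate columns must be scaled to [0, 1]")
        if self.Y is not None:
            self.Y = np.asarray(self.Y)
            if not np.isin(self.Y, [0, 1]).all():
                raise ValueError("phenotypes must be binary 0/1 with no missing values")
            self.Y = self.Y.astype(float)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    def mask(self, split: str | None) -> np.ndarray:
        """Boolean sample mask for ``"train"``, ``"test"`` or ``None`` (all)."""
        if split is None or split == "all" or self.split is None:
            return np.ones(self.n_samples, dtype=bool)
        return self.split == split


@dataclass
class GenotypeBlock:
    """A rare-variant dosage block: variants, positions, MAFs, and dosages."""

    variant_ids: list[str]
    contigs: list[str]
    positions: np.ndarray  # 1-based VCF POS
    ref: list[str]
    alt: list[str]
    G: np.ndarray  # n x p dosages, np.nan marks missing
    maf: np.ndarray  # per-variant observed MAF on non-missing calls
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.G.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError("G must be n_samples x n_variants")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "GenotypeBlock":
        return GenotypeBlock(
            list(self.variant_ids),
            list(self.contigs),
            self.positions.copy(),
            list(self.ref),
            list(self.alt),
            self.G.copy(),
            self.maf.copy(),
            list(self.sample_ids),
        )


@dataclass
class GeneVariantSet:
    """One gene's rare-variant block with its annotation matrix.

    ``Z`` is ``p x q`` with entries in [0, 1]; ``G`` is the ``n x p`` dosage
    sub-matrix restricted to this gene's variants for one cell type.
    """

    gene: str
    G: np.ndarray
    maf: np.ndarray
    Z: np.ndarray
    variant_ids: list[str] = field(default_factory=list)
    annotation_names: list[str] = field(default_factory=list)
    cell_type: str = "all"

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        p = self.G.shape[1]
        if self.Z.shape[0] != p or len(self.maf) != p:
            raise ValueError(f"gene {self.gene}: G, Z, maf variant dimensions disagree")

    @property
    def n_variants(self) -> int:
        return self.G.shape[1]

    @property
    def n_annotations(self) -> int:
        return self.Z.shape[1]


@dataclass
class GeneParams:
    """Per-gene coefficients: covariate vector alpha_g and scalar effect w_g."""

    gene: str
    alpha: np.ndarray
    w: float

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.w)):
            raise ValueError(f"gene {self.gene}: non-finite parameters")


class GlobalParams:
    """Annotation-weight simplex tau = (tau_0, tau_1, ..., tau_q).

    ``tau_0`` is the intercept weight; the remaining ``q`` entries weight the
    annotation columns. All entries are nonnegative and sum to one, which pins
    the overall scale and keeps gene effects w_g identifiable.
    """

    def __init__(self, tau: Sequence[float]):
        tau = np.asarray(tau, dtype=float)
        if tau.ndim != 1 or (tau < 0).any():
            raise ValueError("tau must be a 1-D nonnegative vector")
        if abs(tau.sum() - 1.0) > 1e-8:
            raise ValueError(f"tau must sum to 1 (got {tau.sum():.10f})")
        self.tau = tau

    @property
    def intercept(self) -> float:
        return float(self.tau[0])

    @property
    def annotation_weights(self) -> np.ndarray:
        return self.tau[1:]

    def __len__(self) -> int:
        return len(self.tau)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GlobalParams(tau={np.array2string(self.tau, precision=4)})"


@dataclass
class JointFitResult:
    """Output of the joint variational fit (Step 1)."""

    genes: list[str]
    tau_hat: GlobalParams
    alpha_mean: np.ndarray  # M x c
    alpha_sd: np.ndarray
    w_mean: np.ndarray  # M
    w_sd: np.ndarray
    elbo_trace: np.ndarray
    config: dict

    def __post_init__(self) -> None:
        if not np.isfinite(self.elbo_trace).all():
            raise ValueError("non-finite ELBO trace")
        if (self.alpha_sd < 0).any() or (self.w_sd < 0).any():
            raise ValueError("posterior sds must be nonnegative")


@dataclass
class GeneTestResult:
    """Per-gene likelihood-ratio test result (Step 2)."""

    gene: str
    w_hat: float
    alpha_hat: np.ndarray
    loglik_combined: float
    loglik_covariates_only: float
    lr_stat: float
    p_value: float
    n_variants: int
    cell_type: str = "all"
    converged: bool = True
    significant: bool | None = None


@dataclass
class SimTruth:
    """Ground-truth parameter set behind one synthetic phenotype draw."""

    genes: list[str]
    alpha_true: np.ndarray  # M x c
    w_true: np.ndarray  # M
    tau_true: np.ndarray  # simplex (q+1, or q without intercept)
    beta_true: dict[str, np.ndarray]
    Y_sim: np.ndarray  # n x M, one phenotype vector per gene
    heritability_per_gene: np.ndarray
    heritability_estimate: float
    include_intercept_tau: bool
    seed: int

    def __post_init__(self) -> None:
        if abs(self.tau_true.sum() - 1.0) > 1e-8 or (self.tau_true < 0).any():
            raise ValueError("tau_true must lie on the simplex")
        if not np.isin(self.Y_sim, [0, 1]).all():
            raise ValueError("simulated phenotypes must be binary")
        if not 0.0 <= self.heritability_estimate <= 1.0:
            raise ValueError("heritability must be a fraction")


def results_to_frame(results: Sequence[GeneTestResult]) -> pd.DataFrame:
    """Tidy per-gene result table (gene, cell_type, n_variants, w, LR, p, ...)."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "cell_type": [r.cell_type for r in results],
            "n_variants": [r.n_variants for r in results],
            "w_g": [r.w_hat for r in results],
            "lr_stat": [r.lr_stat for r in results],
            "p_value": [r.p_value for r in results],
            "converged": [r.converged for r in results],
            "significant": [r.significant for r in results],
        }
    )
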