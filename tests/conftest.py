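"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from gruyere.simulation import SyntheticCohortSpec, generate_cohort


def nr_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-12):
    """Plain Newton-Raphson logistic regression (no ridge): independent oracle.

    Returns (coefficients, log-likelihood). Deliberately written from the
    textbook update so it shares no code with the package's IRLS.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        W = p * (1.0 - p)
        H = X.T @ (X * W[:, None])
        g = X.T @ (y - p)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = X @ beta
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, ll


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticCohortSpec:
    """A fast cohort for inference tests: 800 samples, 8 genes, 40 variants."""
    return SyntheticCohortSpec(
        n_samples=800, n_genes=8, variants_per_gene=40, n_covariates=5,
        n_annotations=4,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec, seed=101)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
{records}
"""


def write_toy_vcf(path, genotype_rows: list[tuple], n_samples: int):
    """Write a minimal GT-only VCF; genotype_rows are (pos, ref, alt, gts)."""
    samples = "\t".join(f"S{i}" for i in range(n_samples))
    recs = []
    for pos, ref, alt, gts in genotype_rows:
        gt_fields = "\t".join(gts)
        recs.append(f"1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt_fields}")
    path.write_text(TOY_VCF.format(samples=samples, records="\n".join(recs)))
    return path
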