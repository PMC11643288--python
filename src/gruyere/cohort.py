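"""Cohort input, genotype QC, imputation, and the stratified train/test split.

Readers accept VCF (v4.x, GT field, via :mod:`cyvcf2`) and a whitespace- or
tab-delimited dosage text format (one row per sample, one column per variant,
header row of ``chr:pos:ref:alt`` variant ids, first column ``sample_id``).
Covariates and phenotypes come from a TSV keyed by a mandatory ``sample_id``
column. Every filter logs the number of records it removes.

QC order is fixed: samples with excess missingness are removed first, then
variants with a low call rate; MAFs are recomputed after sample removal by
default (``recompute_maf``). Missing dosages are imputed with the expected
dosage ``2 * MAF`` (configurable to the raw MAF).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datatypes import CohortData, GenotypeBlock

logger = logging.getLogger(__name__)

__all__ = [
    "load_genotypes",
    "load_covariates",
    "qc_filter",
    "impute_missing",
    "split_train_test",
    "minmax_scale_columns",
]


def _observed_maf(G: np.ndarray) -> np.ndarray:
    """Per-variant alt-allele frequency on non-missing calls (NaN if none)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(G, axis=0) / 2.0


def _orient_minor(G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flip dosages so they count the per-site minor allele; return (G, maf, flipped)."""
    af = _observed_maf(G)
    flipped = af > 0.5
    G = G.copy()
    G[:, flipped] = 2.0 - G[:, flipped]
    maf = np.where(flipped, 1.0 - af, af)
    return G, maf, flipped


def load_genotypes(
    path: str, format: str = "vcf", maf_max: float = 0.05
) -> GenotypeBlock:
    """Read a genotype file, keeping biallelic variants with observed MAF <= maf_max.

    Multiallelic records are dropped. The minor allele is defined per site:
    dosages count the less frequent allele, with MAF computed over non-missing
    calls. An empty surviving block triggers a warning, not an error.
    """
    if not 0 < maf_max <= 0.5:
        raise ValueError("maf_max must lie in (0, 0.5]")
    if format == "vcf":
        ids, contigs, positions, ref, alt, cols, samples = _read_vcf(path)
    elif format in ("dosage", "plink-text"):
        ids, contigs, positions, ref, alt, cols, samples = _read_dosage_text(path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")

    n_multi = getattr(_read_vcf, "_last_multiallelic", 0) if format == "vcf" else 0
    G = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    G, maf, _ = _orient_minor(G)
    keep = np.flatnonzero(~np.isnan(maf) & (maf <= maf_max))
    n_dropped = G.shape[1] - len(keep)
    logger.info(
        "load_genotypes: %d variants read, %d multiallelic dropped, "
        "%d above MAF %.3g dropped, %d retained",
        G.shape[1], n_multi, n_dropped, maf_max, len(keep),
    )
    if len(keep) == 0:
        warnings.warn("all variants removed by the MAF filter; block is empty")
    return GenotypeBlock(
        [ids[i] for i in keep],
        [contigs[i] for i in keep],
        positions[keep] if len(keep) else np.array([], dtype=int),
        [ref[i] for i in keep],
        [alt[i] for i in keep],
        G[:, keep],
        maf[keep],
        samples,
    )


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    ids, contigs, positions, ref, alt, cols = [], [], [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0/1/2 are alt-allele dosages, 3 is missing
        d = v.gt_types.astype(float)
        d[d == 3] = np.nan
        ids.append(f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}")
        contigs.append(v.CHROM)
        positions.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        cols.append(d)
    _read_vcf._last_multiallelic = n_multi
    return ids, contigs, np.asarray(positions, dtype=int), ref, alt, cols, samples


def _parse_variant_id(vid: str) -> tuple[str, int, str, str]:
    parts = vid.split(":")
    if len(parts) == 4:
        try:
            return parts[0], int(parts[1]), parts[2], parts[3]
        except ValueError:
            pass
    return "", 0, "N", "N"


def _read_dosage_text(path):
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"unparseable dosage file {path}: {exc}") from exc
    if df.columns[0] != "sample_id":
        raise ValueError("dosage text format requires a leading 'sample_id' column")
    samples = df["sample_id"].tolist()
    ids = list(df.columns[1:])
    vals = df.iloc[:, 1:].replace({"NA": np.nan, ".": np.nan, "-9": np.nan})
    try:
        G = vals.astype(float).to_numpy()
    except ValueError as exc:
        bad = vals.apply(pd.to_numeric, errors="coerce").isna() & vals.notna()
        row = int(np.argwhere(bad.to_numpy())[0][0]) + 2  # +header +1-based
        raise ValueError(f"unparseable dosage value at line {row} of {path}") from exc
    ok = np.isnan(G) | np.isin(G, [0.0, 1.0, 2.0])
    if not ok.all():
        row = int(np.argwhere(~ok)[0][0]) + 2
        raise ValueError(f"dosage outside {{0,1,2,missing}} at line {row} of {path}")
    parsed = [_parse_variant_id(v) for v in ids]
    contigs = [p[0] for p in parsed]
    positions = np.array([p[1] for p in parsed], dtype=int)
    ref = [p[2] for p in parsed]
    alt = [p[3] for p in parsed]
    cols = [G[:, j] for j in range(G.shape[1])]
    return ids, contigs, positions, ref, alt, cols, samples


def minmax_scale_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Scale each numeric column to [0, 1]; constant columns must already fit."""
    out = df.copy()
    for c in out.columns:
        col = out[c].astype(float)
        lo, hi = col.min(), col.max()
        if hi > lo:
            out[c] = (col - lo) / (hi - lo)
        elif 0.0 <= lo <= 1.0:
            out[c] = col  # constant column already in range (e.g. intercept)
        else:
            raise ValueError(f"constant covariate column {c!r} outside [0, 1]")
    return out


def load_covariates(
    path: str,
    phenotype_col: str | None = "phenotype",
    ancestry_col: str | None = None,
) -> CohortData:
    """Load a covariate/phenotype TSV into a :class:`CohortData`.

    Requires a ``sample_id`` column; every remaining numeric column is min-max
    scaled to [0, 1]. Missing phenotypes are a hard error.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("covariate table must contain a 'sample_id' column")
    sample_ids = df["sample_id"].astype(str).tolist()
    Y = None
    if phenotype_col is not None and phenotype_col in df.columns:
        if df[phenotype_col].isna().any():
            raise ValueError("missing phenotypes are not allowed")
        Y = df[phenotype_col].to_numpy()
    ancestry = None
    if ancestry_col is not None and ancestry_col in df.columns:
        ancestry = df[ancestry_col].astype(str).to_numpy()
    drop = {"sample_id", phenotype_col, ancestry_col} - {None}
    cov = df[[c for c in df.columns if c not in drop]]
    cov = minmax_scale_columns(cov)
    return CohortData(
        sample_ids, Y, cov.to_numpy(dtype=float), list(cov.columns), ancestry=ancestry
    )


def qc_filter(
    block: GenotypeBlock,
    cohort: CohortData | None = None,
    sample_missing_max: float = 0.10,
    variant_callrate_min: float = 0.90,
    recompute_maf: bool = True,
) -> tuple[GenotypeBlock, CohortData | None]:
    """Remove high-missingness samples, then low-call-rate variants.

    Missingness is computed on the raw (pre-imputation) dosages. Sample
    removal happens first; variant call rates are then computed over the
    surviving samples, so the operation is idempotent. MAFs are recomputed on
    the surviving samples unless ``recompute_maf`` is False.
    """
    for name, thr in (
        ("sample_missing_max", sample_missing_max),
        ("variant_callrate_min", variant_callrate_min),
    ):
        if not 0 < thr <= 1:
            raise ValueError(f"{name} must lie in (0, 1]")
    G = block.G
    miss = np.isnan(G)
    if G.shape[1]:
        sample_keep = miss.mean(axis=1) <= sample_missing_max
    else:
        sample_keep = np.ones(G.shape[0], dtype=bool)
    G = G[sample_keep]
    if G.shape[0]:
        callrate = 1.0 - np.isnan(G).mean(axis=0)
    else:
        callrate = np.zeros(G.shape[1])
    variant_keep = callrate >= variant_callrate_min
    logger.info(
        "qc_filter: removed %d/%d samples, %d/%d variants",
        int((~sample_keep).sum()), len(sample_keep),
        int((~variant_keep).sum()), len(variant_keep),
    )
    G = G[:, variant_keep]
    idx = np.flatnonzero(variant_keep)
    maf = _observed_maf(G) if recompute_maf else block.maf[idx]
    new_block = GenotypeBlock(
        [block.variant_ids[i] for i in idx],
        [block.contigs[i] for i in idx],
        block.positions[idx],
        [block.ref[i] for i in idx],
        [block.alt[i] for i in idx],
        G,
        maf,
        [s for s, k in zip(block.sample_ids, sample_keep) if k],
    )
    new_cohort = cohort
    if cohort is not None and not sample_keep.all():
        keep_ids = set(new_block.sample_ids)
        sel = np.array([s in keep_ids for s in cohort.sample_ids])
        new_cohort = CohortData(
            [s for s, k in zip(cohort.sample_ids, sel) if k],
            None if cohort.Y is None else cohort.Y[sel],
            cohort.X[sel],
            cohort.covariate_names,
            split=None if cohort.split is None else cohort.split[sel],
            ancestry=None if cohort.ancestry is None else cohort.ancestry[sel],
        )
    return new_block, new_cohort


def impute_missing(block: GenotypeBlock, mode: str = "dosage") -> GenotypeBlock:
    """Fill missing dosages from the variant's observed MAF.

    ``mode="dosage"`` (default) imputes the expected dosage ``2 * MAF``;
    ``mode="maf"`` imputes the MAF itself. A variant with no observed calls
    has an undefined MAF and raises.
    """
    if mode not in ("dosage", "maf"):
        raise ValueError("mode must be 'dosage' or 'maf'")
    if np.isnan(block.maf).any():
        bad = [block.variant_ids[i] for i in np.flatnonzero(np.isnan(block.maf))]
        raise ValueError(f"MAF undefined (zero observed calls) for: {bad[:5]}")
    if not np.isnan(block.G).any():
        return block
    out = block.copy()
    fill = (2.0 if mode == "dosage" else 1.0) * out.maf
    miss = np.isnan(out.G)
    out.G[miss] = np.broadcast_to(fill, out.G.shape)[miss]
    logger.info("impute_missing: filled %d missing entries", int(miss.sum()))
    return out


def split_train_test(
    cohort: CohortData, train_frac: float = 0.8, seed: int = 0
) -> CohortData:
    """Assign train/test labels, stratified by ancestry when available.

    Each stratum contributes ``round(train_frac * size)`` training samples;
    a stratum with fewer than two samples goes entirely to train (with a
    warning). Deterministic for a fixed seed.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = cohort.n_samples
    strata = cohort.ancestry if cohort.ancestry is not None else np.zeros(n, dtype=int)
    split = np.empty(n, dtype=object)
    for s in pd.unique(strata):
        idx = np.flatnonzero(strata == s)
        if len(idx) < 2:
            warnings.warn(f"stratum {s!r} has <2 samples; placed wholly in train")
            split[idx] = "train"
            continue
        n_train = int(np.floor(train_frac * len(idx) + 0.5))
        perm = rng.permutation(idx)
        split[perm[:n_train]] = "train"
        split[perm[n_train:]] = "test"
    return CohortData(
        cohort.sample_ids,
        cohort.Y,
        cohort.X,
        cohort.covariate_names,
        split=split.astype(str),
        ancestry=cohort.ancestry,
    )
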