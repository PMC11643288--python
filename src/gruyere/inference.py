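"""Two-step fitting: joint variational estimation of tau, then per-gene LRTs.

Step 1 (:func:`fit_joint`) maximizes the evidence lower bound (ELBO) of the
hierarchical model over a screened gene subset by stochastic variational
inference: mean-field normal guides for the per-gene covariate coefficients
alpha_g and gene effects w_g, and a point (delta) guide for the shared
annotation-weight simplex tau, parameterized through an unconstrained softmax.
Gradients are single-sample reparameterized Monte Carlo estimates with the
Bernoulli-logit likelihood term and the Gaussian KL terms computed
analytically; optimization is Adam (default learning rate 0.1, 300 epochs).

Step 2 (:func:`fit_per_gene`) holds tau fixed, collapsing each gene's model to
an ordinary logistic regression on covariates plus a single fixed per-variant
score; gene-level p-values come from a likelihood-ratio test against the
covariate-only null, referred to chi-square with one degree of freedom.

The per-gene burden score precomputation exploits the bilinear structure of
the variant effect: with Gw = G * w_j (columns weighted by the MAF kernel),
the genotype term of the linear predictor is w_g * D tau where
D = [Gw 1, Gw Z] is an n x (q+1) matrix that never changes during training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, softmax

from .datatypes import (
    CohortData,
    GeneTestResult,
    GeneVariantSet,
    GlobalParams,
    JointFitResult,
)
from .model import bernoulli_loglik, maf_weight

logger = logging.getLogger(__name__)

__all__ = [
    "PriorConfig",
    "screen_genes",
    "burden_screen",
    "fit_joint",
    "fit_per_gene",
    "lrt_pvalue",
    "bonferroni",
]


@dataclass
class PriorConfig:
    """Prior settings for the joint fit.

    ``alpha_scale`` / ``w_scale`` are the standard deviations of the Normal
    priors on alpha_g and w_g (default 1). ``w_prior="gamma"`` switches the
    gene-effect prior to Gamma(shape, rate) on the positive half-line with a
    log-normal mean-field guide — used to probe robustness when the fitted
    prior disagrees with the data-generating distribution.
    ``dirichlet_concentration`` defaults to 1/len(tau).
    """

    alpha_scale: float = 1.0
    w_prior: str = "normal"  # "normal" | "gamma"
    w_scale: float = 1.0
    w_gamma_shape: float = 1.0
    w_gamma_rate: float = 1.0
    dirichlet_concentration: float | None = None


def screen_genes(
    pvalues: Mapping[str, float] | pd.Series, threshold: float = 0.01
) -> list[str]:
    """Genes passing a lenient per-gene significance screen (p < threshold).

    The p-values typically come from an external rare-variant test; absent
    one, :func:`burden_screen` provides a built-in covariate-adjusted
    MAF-weighted burden LRT.
    """
    pv = pd.Series(dict(pvalues) if not isinstance(pvalues, pd.Series) else pvalues)
    if pv.empty:
        raise ValueError("empty p-value table")
    if ((pv <= 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    survivors = list(pv.index[pv < threshold])
    if not survivors:
        raise ValueError(
            f"no genes pass the screen at p < {threshold}; loosen the threshold"
        )
    return survivors


def burden_screen(
    cohort: CohortData,
    gene_sets: Mapping[str, GeneVariantSet],
    split: str | None = "train",
) -> pd.Series:
    """Built-in screening p-values: MAF-weighted burden added to the covariate model.

    For each gene the burden score ``G @ w_j`` joins the covariate logistic
    regression; the LRT against the covariate-only null gives the screen
    p-value.
    """
    mask = cohort.mask(split)
    X, y = cohort.X[mask], cohort.Y[mask]
    a0, ll0, _ = _logistic_irls(X, y)
    out = {}
    for gene, gvs in gene_sets.items():
        burden = gvs.G[mask] @ maf_weight(gvs.maf)
        coef, ll1, conv = _logistic_irls(np.column_stack([X, burden]), y)
        out[gene] = lrt_pvalue(ll1, ll0) if conv else np.nan
    return pd.Series(out, name="p_value")


def _prep_design(gvs: GeneVariantSet, include_intercept: bool = True) -> np.ndarray:
    """Precompute D = [Gw 1, Gw Z] so the genotype logit term is w_g * (D tau).

    Without the intercept component the burden column ``Gw 1`` is dropped and
    tau lives on the q-simplex.
    """
    Gw = gvs.G * maf_weight(gvs.maf)
    if include_intercept:
        return np.column_stack([Gw.sum(axis=1), Gw @ gvs.Z])
    return Gw @ gvs.Z


class _Adam:
    def __init__(self, shapes, lr):
        self.lr, self.t = lr, 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p += self.lr * mhat / (np.sqrt(vhat) + eps)  # ascent on the ELBO


def fit_joint(
    cohort: CohortData,
    gene_sets: Mapping[str, GeneVariantSet],
    priors: PriorConfig | None = None,
    epochs: int = 300,
    lr: float = 0.1,
    seed: int = 0,
    n_posterior_samples: int = 50,
    phenotypes: np.ndarray | None = None,
    split: str | None = "train",
    include_intercept_tau: bool = True,
) -> JointFitResult:
    """Jointly fit tau, alpha_g, and w_g by SVI over the screened genes.

    Parameters
    ----------
    phenotypes
        Optional ``n x M`` matrix of per-gene phenotype vectors (one column
        per gene, in ``gene_sets`` order); when ``None`` the cohort's single
        phenotype vector is shared by every gene's likelihood, as with real
        case-control data.
    split
        Which samples to train on (``"train"`` by default when the cohort
        carries split labels; ``None`` for all).
    include_intercept_tau
        When True (default), tau has an intercept component tau_0 and lives
        on the (q+1)-simplex; when False the effect is the pure annotation
        sum and tau lives on the q-simplex.

    Returns
    -------
    JointFitResult
        Point estimate of tau, per-gene posterior means/sds for alpha_g and
        w_g, and the per-epoch ELBO trace. Deterministic for a fixed seed.
    """
    priors = priors or PriorConfig()
    genes = list(gene_sets)
    M = len(genes)
    if M < 2:
        raise ValueError("joint fit requires at least 2 screened genes")
    qs = {gene_sets[g].n_annotations for g in genes}
    if len(qs) != 1:
        raise ValueError("all genes must share the same annotation dimension q")
    q = qs.pop()
    mask = cohort.mask(split)
    X = cohort.X[mask]
    n, c = X.shape
    D = np.stack(
        [_prep_design(gene_sets[g], include_intercept_tau)[mask] for g in genes]
    )  # M x n x K
    if phenotypes is not None:
        Y = np.asarray(phenotypes, dtype=float)[mask].T  # M x n
    else:
        if cohort.Y is None:
            raise ValueError("cohort carries no phenotypes")
        Y = np.broadcast_to(cohort.Y[mask], (M, n))

    K = q + 1 if include_intercept_tau else q
    conc = priors.dirichlet_concentration or 1.0 / K
    gamma_guide = priors.w_prior == "gamma"
    if priors.w_prior not in ("normal", "gamma"):
        raise ValueError(f"unknown w prior {priors.w_prior!r}")

    rng = np.random.default_rng(seed)
    # variational parameters: means and log-sds (init_scale 0.1), tau logits
    m_a = np.zeros((M, c))
    ls_a = np.full((M, c), np.log(0.1))
    m_w = np.zeros(M) if not gamma_guide else np.full(M, np.log(0.5))
    ls_w = np.full(M, np.log(0.1))
    theta = np.zeros(K)
    params = [m_a, ls_a, m_w, ls_w, theta]
    opt = _Adam([p.shape for p in params], lr)

    elbo_trace = np.empty(epochs)
    worse = 0
    for epoch in range(epochs):
        tau = softmax(theta)
        s_a, s_w = np.exp(ls_a), np.exp(ls_w)
        eps_a = rng.standard_normal((M, c))
        eps_w = rng.standard_normal(M)
        alpha = m_a + s_a * eps_a
        u_w = m_w + s_w * eps_w
        w = np.exp(u_w) if gamma_guide else u_w

        score = D @ tau  # M x n
        eta = alpha @ X.T + w[:, None] * score
        mu = expit(eta)
        resid = Y - mu  # d loglik / d eta
        loglik = float(np.sum(Y * eta - np.logaddexp(0.0, eta)))

        g_alpha = resid @ X  # M x c
        g_w = np.einsum("mn,mn->m", resid, score)
        g_tau = np.einsum("mn,mnk->k", resid * w[:, None], D)

        # Gaussian KL for alpha (and w under the normal prior), analytic
        kl_a = np.sum(
            0.5 * (m_a**2 + s_a**2) / priors.alpha_scale**2 - ls_a
            + np.log(priors.alpha_scale) - 0.5
        )
        d_m_a = g_alpha - m_a / priors.alpha_scale**2
        d_ls_a = g_alpha * (s_a * eps_a) + 1.0 - s_a**2 / priors.alpha_scale**2

        if gamma_guide:
            # log-normal guide on w: latent u ~ N(m, s^2), w = exp(u);
            # ELBO term E[log Gamma(w) + u] + entropy(q(u)); MC for the mean.
            sh, ra = priors.w_gamma_shape, priors.w_gamma_rate
            logp_w = float(np.sum((sh - 1) * u_w - ra * w + u_w))  # consts dropped
            d_u = g_w * w + sh - ra * w
            d_m_w = d_u
            d_ls_w = d_u * (s_w * eps_w) + 1.0
            kl_w_term = -(logp_w + float(np.sum(ls_w)))  # -(E log p + entropy)+const
        else:
            kl_w = np.sum(
                0.5 * (m_w**2 + s_w**2) / priors.w_scale**2 - ls_w
                + np.log(priors.w_scale) - 0.5
            )
            d_m_w = g_w - m_w / priors.w_scale**2
            d_ls_w = g_w * (s_w * eps_w) + 1.0 - s_w**2 / priors.w_scale**2
            kl_w_term = float(kl_w)

        # Dirichlet(conc) log-prior on tau, chained through the softmax
        tau_c = np.clip(tau, 1e-10, None)
        logp_tau = float(np.sum((conc - 1.0) * np.log(tau_c)))
        v = g_tau + (conc - 1.0) / tau_c
        d_theta = tau * (v - float(v @ tau))

        elbo = loglik - float(kl_a) - kl_w_term + logp_tau
        if not np.isfinite(elbo):
            raise RuntimeError(f"non-finite ELBO at epoch {epoch}")
        elbo_trace[epoch] = elbo
        worse = worse + 1 if epoch and elbo < elbo_trace[epoch - 1] else 0
        if worse == 50:
            warnings.warn(f"ELBO worsened for 50 consecutive epochs (epoch {epoch})")

        opt.step(params, [d_m_a, d_ls_a, d_m_w, d_ls_w, d_theta])

    tau_hat = GlobalParams(softmax(theta) / softmax(theta).sum())
    if gamma_guide:
        draws = np.exp(m_w + np.exp(ls_w) * rng.standard_normal((n_posterior_samples, M)))
        w_mean, w_sd = draws.mean(axis=0), draws.std(axis=0)
    else:
        w_mean, w_sd = m_w.copy(), np.exp(ls_w)
    return JointFitResult(
        genes=genes,
        tau_hat=tau_hat,
        alpha_mean=m_a,
        alpha_sd=np.exp(ls_a),
        w_mean=w_mean,
        w_sd=w_sd,
        elbo_trace=elbo_trace,
        config={
            "epochs": epochs, "lr": lr, "seed": seed,
            "n_posterior_samples": n_posterior_samples,
            "priors": vars(priors).copy(), "n_train": n,
            "include_intercept_tau": include_intercept_tau,
        },
    )


def _logistic_irls(
    Xd: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-10,
    sep_norm: float = 50.0,
) -> tuple[np.ndarray, float, bool]:
    """Newton/IRLS logistic fit with a tiny ridge for stability.

    Returns (coefficients, log-likelihood, converged). Separation is flagged
    when the coefficient norm exceeds ``sep_norm``; step halving guards
    against overshooting.
    """
    k = Xd.shape[1]
    beta = np.zeros(k)
    ll = bernoulli_loglik(y, Xd @ beta) - 0.5 * ridge * beta @ beta
    converged = False
    eye = ridge * np.eye(k)
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = expit(eta)
        grad = Xd.T @ (y - mu) - ridge * beta
        Wd = np.clip(mu * (1 - mu), 1e-10, None)
        H = (Xd * Wd[:, None]).T @ Xd + eye
        step = np.linalg.solve(H, grad)
        # step halving on penalized log-likelihood
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = bernoulli_loglik(y, Xd @ cand) - 0.5 * ridge * cand @ cand
            if ll_new >= ll - 1e-12:
                break
            t /= 2
        beta, ll = beta + t * step, ll_new
        if np.max(np.abs(t * step)) < tol:
            converged = True
            break
    if np.linalg.norm(beta) > sep_norm:
        converged = False
    return beta, bernoulli_loglik(y, Xd @ beta), converged


def fit_per_gene(
    gvs: GeneVariantSet,
    cohort: CohortData,
    tau: GlobalParams | np.ndarray,
    split: str | None = "train",
) -> GeneTestResult:
    """Per-gene logistic LRT with tau held fixed.

    The gene's variants collapse to one fixed score per sample,
    ``G @ (w_j * (tau_0 + Z tau))``, whose coefficient is the gene effect
    w_g. The LRT compares this combined model against the covariate-only
    null; the statistic is referred to chi-square(1). Non-convergence or
    separation yields a flagged result with an NA p-value rather than an
    exception.
    """
    if gvs.n_variants < 1:
        raise ValueError(f"gene {gvs.gene} has no variants")
    t = tau.tau if isinstance(tau, GlobalParams) else np.asarray(tau, dtype=float)
    mask = cohort.mask(split)
    X, y = cohort.X[mask], cohort.Y[mask]
    w_j = maf_weight(gvs.maf)
    if len(t) == gvs.n_annotations + 1:
        b = w_j * (t[0] + gvs.Z @ t[1:])
    elif len(t) == gvs.n_annotations:
        b = w_j * (gvs.Z @ t)
    else:
        raise ValueError("tau length incompatible with annotation dimension")
    score = gvs.G[mask] @ b
    alpha0, ll0, conv0 = _logistic_irls(X, y)
    coef, ll1, conv1 = _logistic_irls(np.column_stack([X, score]), y)
    converged = conv0 and conv1
    if converged:
        lr_stat = 2.0 * (ll1 - ll0)
        if lr_stat < -1e-8:
            raise ValueError(
                f"gene {gvs.gene}: combined log-likelihood below the nested null"
            )
        lr_stat = max(lr_stat, 0.0)
        p = float(stats.chi2.sf(lr_stat, df=1))
    else:
        lr_stat, p = np.nan, np.nan
    return GeneTestResult(
        gene=gvs.gene,
        w_hat=float(coef[-1]),
        alpha_hat=coef[:-1],
        loglik_combined=ll1,
        loglik_covariates_only=ll0,
        lr_stat=lr_stat,
        p_value=p,
        n_variants=gvs.n_variants,
        cell_type=gvs.cell_type,
        converged=converged,
    )


def lrt_pvalue(ll_combined: float, ll_null: float, slack: float = 1e-8) -> float:
    """Chi-square(1) survival p-value for LR = 2 (ll_combined - ll_null)."""
    lr = 2.0 * (ll_combined - ll_null)
    if lr < -slack:
        raise ValueError(
            f"nested-model violation: combined log-likelihood {ll_combined} "
            f"below null {ll_null}"
        )
    return float(stats.chi2.sf(max(lr, 0.0), df=1))


def bonferroni(
    results: Sequence[GeneTestResult], alpha: float = 0.05
) -> dict[str, float]:
    """Mark genome-wide significance per cell type at p < alpha / n_genes.

    The comparison is strict: a p-value exactly at the threshold is not
    significant. Returns the threshold used per cell type; the calls are
    written onto each result's ``significant`` field (NA p-values stay None).
    """
    by_ct: dict[str, list[GeneTestResult]] = {}
    for r in results:
        by_ct.setdefault(r.cell_type, []).append(r)
    thresholds = {}
    for ct, rs in by_ct.items():
        thr = alpha / len(rs)
        thresholds[ct] = thr
        for r in rs:
            r.significant = bool(r.p_value < thr) if np.isfinite(r.p_value) else None
    return thresholds
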