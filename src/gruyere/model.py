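"""Model primitives: MAF weights, variant effects, and the linear predictor.

The per-gene generalized linear model is

    logit mu_i = X_i . alpha_g + G_i . beta_g

with the per-variant effect built deterministically from a scalar gene effect
w_g, a MAF-based variant weight w_j, scaled annotations Z, and the shared
annotation-weight simplex tau:

    beta_gj = w_g * w_j * (tau_0 + sum_k Z_jk tau_k)

Everything here is a pure function; randomness and optimization live in
:mod:`gruyere.inference`.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit

from .datatypes import GlobalParams

__all__ = ["maf_weight", "variant_effect", "linear_predictor", "sigmoid"]

sigmoid = expit


def maf_weight(maf, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(a, b) density evaluated at the minor-allele frequency.

    With the default Beta(1, 25) kernel this is ``25 * (1 - maf)**24``, a
    strictly decreasing weight that up-weights rarer variants; ``maf_weight(0)
    == 25``. Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any MAF falls outside [0, 1].
    """
    maf = np.asarray(maf, dtype=float)
    if ((maf < 0) | (maf > 1)).any() or not np.isfinite(maf).all():
        raise ValueError("MAF must lie in [0, 1]")
    out = stats.beta.pdf(maf, a, b)
    return out if out.ndim else float(out)


def variant_effect(
    w_g: float,
    w_j: np.ndarray,
    Z: np.ndarray,
    tau: GlobalParams | np.ndarray,
    include_intercept: bool = True,
) -> np.ndarray:
    """Per-variant effect sizes beta_gj = w_g * w_j * (tau_0 + Z tau).

    Parameters
    ----------
    w_g
        Scalar gene effect.
    w_j
        Positive MAF weights, length ``p``.
    Z
        ``p x q`` annotation matrix with entries in [0, 1].
    tau
        Simplex of length ``q + 1`` (intercept first) when
        ``include_intercept``, else length ``q``.
    include_intercept
        If False, the intercept term tau_0 is omitted:
        ``beta = w_g * w_j * (Z tau)``.
    """
    t = tau.tau if isinstance(tau, GlobalParams) else np.asarray(tau, dtype=float)
    w_j = np.asarray(w_j, dtype=float)
    Z = np.asarray(Z, dtype=float)
    q = Z.shape[1]
    expected = q + 1 if include_intercept else q
    if len(t) != expected:
        raise ValueError(f"tau has length {len(t)}, expected {expected}")
    if Z.shape[0] != len(w_j):
        raise ValueError("Z rows must match w_j length")
    if include_intercept:
        score = t[0] + Z @ t[1:]
    else:
        score = Z @ t
    return w_g * w_j * score


def linear_predictor(
    X: np.ndarray, alpha: np.ndarray, G: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """Per-sample logits eta_i = X_i . alpha + G_i . beta.

    Case probabilities are ``sigmoid(eta)``. Raises on non-finite output,
    which in practice means the parameters have diverged.
    """
    X = np.asarray(X, dtype=float)
    G = np.asarray(G, dtype=float)
    if X.shape[1] != len(alpha) or G.shape[1] != len(beta):
        raise ValueError("design/coefficient dimension mismatch")
    eta = X @ np.asarray(alpha, dtype=float) + G @ np.asarray(beta, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor")
    return eta


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Log-likelihood of binary y under logits eta, numerically stable."""
    # log sigma(eta)*y + log(1-sigma(eta))*(1-y) = y*eta - log(1+exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
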