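"""Low-level Gibbs-sampling kernels shared by the linear Bayesian models.

All coordinate sweeps maintain a running residual vector ``r`` equal to
``y - fitted`` over the training observations; each scalar update removes
the coordinate's contribution, draws from its full conditional, and adds
the new contribution back.  Random draws are pre-generated per sweep from a
seeded numpy Generator so runs are bit-reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def ridge_sweep(B, r, b, colsq, prior_prec, inv_s2e, z):
    """One Gibbs sweep over coefficients with independent N(0, 1/prior_prec[l]) priors.

    B : (n, q) design over training observations (Fortran-ordered for speed)
    r : (n,) running residual, updated in place
    b : (q,) coefficients, updated in place
    colsq : (q,) precomputed column sums of squares of B
    prior_prec : (q,) prior precision per coefficient
    z : (q,) standard-normal draws
    """
    n, q = B.shape
    for l in range(q):
        old = b[l]
        dot = 0.0
        for i in range(n):
            dot += B[i, l] * r[i]
        rhs = (dot + colsq[l] * old) * inv_s2e
        prec = colsq[l] * inv_s2e + prior_prec[l]
        new = rhs / prec + z[l] / math.sqrt(prec)
        diff = new - old
        if diff != 0.0:
            for i in range(n):
                r[i] -= B[i, l] * diff
        b[l] = new


@njit(cache=True)
def bayesc_sweep(X, r, beta, gamma, colsq, inv_s2e, inv_s2b, pi, z, u):
    """Joint (gamma_j, beta_j) spike-and-slab update for every marker.

    The inclusion indicator is drawn from its marginal (slab integrated out),
    then the effect from the conditional normal; excluded effects are exactly
    zero.  ``z`` and ``u`` are pre-drawn standard normals and uniforms.
    """
    n, p = X.shape
    log_odds_prior = math.log(pi) - math.log(1.0 - pi)
    for j in range(p):
        old = beta[j]
        dot = 0.0
        for i in range(n):
            dot += X[i, j] * r[i]
        rhs = (dot + colsq[j] * old) * inv_s2e
        prec = colsq[j] * inv_s2e + inv_s2b
        m = rhs / prec
        log_bf = 0.5 * (math.log(inv_s2b) - math.log(prec)) + 0.5 * m * m * prec
        t = log_odds_prior + log_bf
        if t > 35.0:
            p_incl = 1.0
        elif t < -35.0:
            p_incl = 0.0
        else:
            p_incl = 1.0 / (1.0 + math.exp(-t))
        if u[j] < p_incl:
            new = m + z[j] / math.sqrt(prec)
            gamma[j] = 1
        else:
            new = 0.0
            gamma[j] = 0
        diff = new - old
        if diff != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * diff
        beta[j] = new


def draw_scaled_inv_chi2(rng: np.random.Generator, df: float, S: float) -> float:
    """Draw sigma^2 from p(s2) ~ (s2)^-(df/2+1) exp(-S / (2 s2)).

    ``S`` is the product (df x scale) in the scaled-inverse-chi-squared
    convention of the reference whole-genome-regression software: the draw is
    S / chi2(df), equivalently InvGamma(df/2, S/2).
    """
    return S / rng.chisquare(df)


def update_factor(
    codes: np.ndarray,
    n_levels: int,
    counts: np.ndarray,
    r: np.ndarray,
    eff: np.ndarray,
    s2e: float,
    s2f: float,
    rng: np.random.Generator,
) -> None:
    """Exact block-Gibbs update of a one-hot random factor (in place).

    Levels unobserved in the training data get prior draws N(0, s2f), which
    the conjugate formula yields automatically via counts of zero.
    """
    r_plus = r + eff[codes]
    sums = np.bincount(codes, weights=r_plus, minlength=n_levels)
    prec = counts / s2e + 1.0 / s2f
    mean = (sums / s2e) / prec
    eff[:] = mean + rng.standard_normal(n_levels) / np.sqrt(prec)
    r[:] = r_plus - eff[codes]
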