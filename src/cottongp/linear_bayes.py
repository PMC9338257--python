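"""Gibbs samplers for Bayesian whole-genome regression.

Three linear models are provided, each with optional pedigree and
year/experiment random effects:

* **BG-BLUP** — a genomic animal model: phenotype = intercept + u + W alpha
  + Z gamma + e with u ~ N(0, sigma_g^2 G) for a genomic relationship
  matrix G, all variance components carrying scaled-inverse-chi-squared
  hyperpriors (df = 5; scales derived from var(y) and an assumed variance
  share R^2).
* **Bayesian LASSO** — per-marker effects with the double-exponential
  shrinkage prior, represented as the conjugate normal-exponential mixture;
  the squared shrinkage factor lambda^2 carries a Gamma(s, r) hyperprior.
* **Bayes C** — per-marker effects under a spike-and-slab prior with a
  common slab variance sigma_b^2 and inclusion probability pi ~ Beta.

Relationship-matrix random effects are sampled through the eigen-factor
parameterisation u = B b with B = V Lambda^{1/2} from the eigendecomposition
of the (train + test) relationship matrix and b ~ N(0, sigma^2 I).  Test
lines simply contribute no likelihood terms, so their effects are drawn
jointly with the training lines — prediction is "phenotypes treated as
missing" by construction.

Line and observation order are canonicalised (lexicographically sorted)
inside every fit, so results are invariant to input row order and
bit-reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import _gibbs
from .data_io import EnvironmentDesign, GenotypeMatrix, PhenotypeTable
from .relatedness import RelationshipMatrix

__all__ = [
    "PriorConfig",
    "ScaleSet",
    "MCMCSettings",
    "ModelData",
    "PosteriorFit",
    "HeritabilityEstimate",
    "build_scale_parameters",
    "fit_bgblup",
    "fit_bayesian_lasso",
    "fit_bayes_c",
    "estimate_heritability",
    "predict_gebv",
]

_VAR_FLOOR = 1e-10  # lower clamp on variance draws (degenerate-Cholesky guard)


@dataclass
class PriorConfig:
    """Hyperprior settings for the linear models.

    df : degrees of freedom of every scaled-inverse-chi-squared variance
        prior (default 5).
    R2 : assumed share of phenotypic variance explained by the genomic
        component in single-kernel models (default 0.5).
    Rg2, Ra2 : genomic and pedigree variance shares for pedigree-augmented
        BG-BLUP (defaults 0.4 and 0.1).
    lasso_shape : shape s of the Gamma(s, r) hyperprior on lambda^2
        (default 1.1); the rate r is derived from R2 and MSx.
    lasso_fixed_lambda2 : if set, lambda^2 is held fixed at this value
        instead of being sampled (useful for exact-posterior checks).
    bayesc_p0, bayesc_pi0 : Beta prior on pi in counts parameterisation,
        shapes (p0*pi0, p0*(1-pi0)); defaults 50 and 0.5.
    env_share : assumed variance share used to scale the experiment and
        year variance priors (default 0.1 each).
    scales : optional preset :class:`ScaleSet`; when given, scale
        derivation from the data is skipped entirely.
    """

    df: float = 5.0
    R2: float = 0.5
    Rg2: float = 0.4
    Ra2: float = 0.1
    lasso_shape: float = 1.1
    lasso_fixed_lambda2: Optional[float] = None
    bayesc_p0: float = 50.0
    bayesc_pi0: float = 0.5
    env_share: float = 0.1
    scales: Optional["ScaleSet"] = None

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("df must be > 0")
        for name, v in (("R2", self.R2), ("Rg2", self.Rg2), ("Ra2", self.Ra2)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.Rg2 + self.Ra2 >= 1.0:
            raise ValueError("Rg2 + Ra2 must be < 1")


@dataclass
class ScaleSet:
    """Derived scale parameters (the S of S/chi2(df) draws)."""

    S0: float  # residual
    Sg: Optional[float] = None  # genomic kernel
    Sa: Optional[float] = None  # pedigree kernel
    Sb: Optional[float] = None  # Bayes C slab variance
    lasso_rate: Optional[float] = None  # rate r of Gamma(s, r) on lambda^2
    S_env: Optional[float] = None  # experiment / year variances
    MSx: Optional[float] = None


@dataclass
class MCMCSettings:
    """MCMC schedule; the default is the full production schedule
    (50 000 iterations, 10 000 burn-in, thinning 20)."""

    n_iter: int = 50_000
    burn_in: int = 10_000
    thin: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def reduced(cls, seed: int = 0) -> "MCMCSettings":
        """Desk-scale profile for tests and quick runs."""
        return cls(n_iter=5_000, burn_in=1_000, thin=4, seed=seed)


@dataclass
class ModelData:
    """Assembled model inputs over a canonical (sorted) line ordering.

    ``obs_line`` maps each phenotype observation to its row in ``line_ids``;
    repeated records per line share the same genetic effect.
    """

    line_ids: np.ndarray
    y: np.ndarray
    obs_line: np.ndarray
    env: Optional[EnvironmentDesign] = None
    G: Optional[RelationshipMatrix] = None
    A: Optional[RelationshipMatrix] = None
    X: Optional[np.ndarray] = None
    marker_ids: Optional[np.ndarray] = None
    trait: str = "trait"

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.y = np.asarray(self.y, dtype=float)
        self.obs_line = np.asarray(self.obs_line, dtype=int)
        if not np.isfinite(self.y).all():
            raise ValueError("phenotype vector contains non-finite values")
        if len(self.y) != len(self.obs_line):
            raise ValueError("y and obs_line differ in length")
        n = len(self.line_ids)
        for mat, name in ((self.G, "G"), (self.A, "A")):
            if mat is not None and mat.n != n:
                raise ValueError(f"{name} dimension does not match line count")
        if self.X is not None and self.X.shape[0] != n:
            raise ValueError("X row count does not match line count")
        if self.env is not None and len(self.env.experiment_codes) != len(self.y):
            raise ValueError("environment design does not match observation count")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @classmethod
    def from_tables(
        cls,
        phenotypes: PhenotypeTable,
        trait: str,
        genotypes: Optional[GenotypeMatrix] = None,
        G: Optional[RelationshipMatrix] = None,
        A: Optional[RelationshipMatrix] = None,
    ) -> "ModelData":
        """Assemble inputs; lines are the sorted intersection of phenotyped
        lines with the genotyped/related set, observations sorted by
        (line, year, experiment)."""
        sets = []
        if genotypes is not None:
            sets.append(set(genotypes.line_ids))
        if G is not None:
            sets.append(set(G.ids))
        if A is not None:
            sets.append(set(A.ids))
        covered = set.intersection(*sets) if sets else set(phenotypes.line_ids)
        line_ids = sorted(set(phenotypes.line_ids) | covered) if not sets else sorted(covered)
        df = phenotypes.data
        df = df[df["line_id"].isin(line_ids)].copy()
        df["year"] = df["year"].astype(str)
        df["experiment"] = df["experiment"].astype(str)
        df = df[df[trait].notna()]
        df = df.sort_values(["line_id", "year", "experiment"]).reset_index(drop=True)
        pos = {l: i for i, l in enumerate(line_ids)}
        obs_line = df["line_id"].map(pos).to_numpy(dtype=int)
        env = EnvironmentDesign.from_phenotypes(PhenotypeTable(df))
        X = marker_ids = None
        if genotypes is not None:
            gsub = genotypes.subset_lines(line_ids)
            X = gsub.dosages
            marker_ids = gsub.marker_ids
        return cls(
            line_ids=np.asarray(line_ids, dtype=object),
            y=df[trait].to_numpy(dtype=float),
            obs_line=obs_line,
            env=env,
            G=None if G is None else G.subset(line_ids),
            A=None if A is None else A.subset(line_ids),
            X=X,
            marker_ids=marker_ids,
            trait=trait,
        )


@dataclass
class PosteriorFit:
    """Thinned posterior draws plus GEBV summaries.

    ``draws`` maps parameter names to arrays whose first axis indexes the
    stored draws: ``beta0``, ``sigma2_e``, ``sigma2_g``/``sigma2_a`` (kernel
    models), ``sigma2_alpha``/``sigma2_gamma`` (env factors), ``u``/``v``
    (line-level genetic values), ``beta`` (marker effects), ``gamma``
    (inclusion indicators), ``lambda2``, ``pi``.
    """

    model: str
    draws: Dict[str, np.ndarray]
    line_ids: np.ndarray
    gebv_mean: pd.Series
    settings: MCMCSettings
    priors: PriorConfig
    scales: ScaleSet
    train_lines: List[str]
    marker_ids: Optional[np.ndarray] = None
    pip: Optional[pd.Series] = None
    x_center: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_stored(self) -> int:
        return self.draws["beta0"].shape[0]

    def gebv_draws(self) -> np.ndarray:
        """(n_stored, n_lines) array of per-draw GEBVs."""
        g = self.draws["beta0"][:, None] + self.draws["u"]
        if "v" in self.draws:
            g = g + self.draws["v"]
        return g


@dataclass
class HeritabilityEstimate:
    mean: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError("posterior mean h2 outside [0, 1]")
        if self.ci_low > self.ci_high:
            raise ValueError("credible interval bounds out of order")


# ---------------------------------------------------------------------------
# prior scales


def build_scale_parameters(
    y: np.ndarray,
    model: str,
    priors: Optional[PriorConfig] = None,
    mean_diag_g: Optional[float] = None,
    mean_diag_a: Optional[float] = None,
    msx: Optional[float] = None,
) -> ScaleSet:
    """Derive the variance-prior scales from var(y) and the assumed shares.

    * BG-BLUP: S0 = var(y) (1 - R2)(df + 2), Sg = var(y) R2 (df + 2) / mean(diag G).
    * BG-BLUP + pedigree: S0 uses (1 - Rg2 - Ra2); Sg and Sa use Rg2 / Ra2
      over the respective mean matrix diagonals.
    * Bayesian LASSO: residual S0 as above; Gamma rate
      r = (s - 1) / (2 (1 - R2)/R2 MSx).
    * Bayes C: slab scale Sb = var(y) R2 (df + 2) / MSx.

    MSx is the sum of per-marker dosage variances (sample, n-1 denominator).
    """
    priors = priors or PriorConfig()
    if priors.scales is not None:
        return priors.scales
    y = np.asarray(y, dtype=float)
    vy = float(np.var(y, ddof=1)) if y.size > 1 else 0.0
    if vy <= 0.0:
        raise ValueError(
            "var(y) is zero; cannot derive prior scales (supply PriorConfig.scales)"
        )
    df = priors.df
    s_env = vy * priors.env_share * (df + 2.0)
    if model in ("bgblup", "bgblup_pedigree"):
        if mean_diag_g is None:
            raise ValueError("mean_diag_g required for BG-BLUP scales")
        if model == "bgblup":
            S0 = vy * (1.0 - priors.R2) * (df + 2.0)
            Sg = vy * priors.R2 * (df + 2.0) / mean_diag_g
            Sa = None
        else:
            if mean_diag_a is None:
                raise ValueError("mean_diag_a required for pedigree scales")
            S0 = vy * (1.0 - priors.Rg2 - priors.Ra2) * (df + 2.0)
            Sg = vy * priors.Rg2 * (df + 2.0) / mean_diag_g
            Sa = vy * priors.Ra2 * (df + 2.0) / mean_diag_a
        return ScaleSet(S0=S0, Sg=Sg, Sa=Sa, S_env=s_env)
    if model in ("lasso", "bayesc"):
        if msx is None or msx <= 0:
            raise ValueError("positive MSx required for marker-model scales")
        S0 = vy * (1.0 - priors.R2) * (df + 2.0)
        Sa = None
        if mean_diag_a is not None:
            Sa = vy * priors.Ra2 * (df + 2.0) / mean_diag_a
        if model == "lasso":
            rate = (priors.lasso_shape - 1.0) / (
                2.0 * (1.0 - priors.R2) / priors.R2 * msx
            )
            return ScaleSet(S0=S0, Sa=Sa, lasso_rate=rate, S_env=s_env, MSx=msx)
        Sb = vy * priors.R2 * (df + 2.0) / msx
        return ScaleSet(S0=S0, Sa=Sa, Sb=Sb, S_env=s_env, MSx=msx)
    raise ValueError(f"unknown model kind {model!r}")


# ---------------------------------------------------------------------------
# eigen-factor preparation


def _kernel_factor(K: RelationshipMatrix, name: str) -> np.ndarray:
    """Factor B with B B' = K from the eigendecomposition, dropping
    numerically null eigenvalues.  A mildly indefinite matrix is jittered
    once; anything worse is an error."""
    M = K.values
    w, V = np.linalg.eigh(M)
    wmax = max(w.max(), 1.0)
    if w.min() < -1e-6 * wmax:
        M = M + (abs(w.min()) + 1e-8) * np.eye(M.shape[0])
        w, V = np.linalg.eigh(M)
        if w.min() < -1e-8 * wmax:
            raise ValueError(f"{name} matrix is not positive semi-definite")
    keep = w > 1e-10 * wmax
    return V[:, keep] * np.sqrt(w[keep])


# ---------------------------------------------------------------------------
# the shared Gibbs engine


def _resolve_train(data: ModelData, train_lines: Optional[Sequence[str]]):
    if train_lines is None:
        train_set = set(data.line_ids[np.unique(data.obs_line)])
    else:
        train_set = set(train_lines)
        unknown = train_set - set(data.line_ids)
        if unknown:
            raise KeyError(f"training line {sorted(unknown)[0]!r} not in data")
    line_is_train = np.array([l in train_set for l in data.line_ids])
    obs_mask = line_is_train[data.obs_line]
    if obs_mask.sum() < 2:
        raise ValueError("need at least two training observations")
    return line_is_train, obs_mask


def _fit_linear(
    data: ModelData,
    model: str,
    priors: Optional[PriorConfig],
    mcmc: Optional[MCMCSettings],
    use_pedigree: bool,
    train_lines: Optional[Sequence[str]],
    fixed_variances: Optional[Mapping[str, float]] = None,
) -> PosteriorFit:
    priors = priors or PriorConfig()
    mcmc = mcmc or MCMCSettings()
    fixed = dict(fixed_variances or {})
    rng = np.random.default_rng(mcmc.seed)

    line_is_train, obs_mask = _resolve_train(data, train_lines)
    y_t = data.y[obs_mask]
    obs_line_t = data.obs_line[obs_mask]
    n_obs = len(y_t)
    n_lines = data.n_lines

    # --- blocks ----------------------------------------------------------
    is_marker_model = model in ("lasso", "bayesc")
    B_G = B_A = Xc = None
    if model == "bgblup":
        if data.G is None:
            raise ValueError("BG-BLUP requires a genomic relationship matrix")
        B_G = _kernel_factor(data.G, "genomic")
    if is_marker_model:
        if data.X is None:
            raise ValueError("marker models require a dosage matrix")
        if data.X.shape[1] == 0:
            raise ValueError("no markers in the dosage matrix")
        x_center = data.X[line_is_train].mean(axis=0)
        Xc = data.X - x_center
    if use_pedigree:
        if data.A is None:
            raise ValueError("use_pedigree=True requires a pedigree matrix A")
        B_A = _kernel_factor(data.A, "pedigree")

    # --- prior scales ----------------------------------------------------
    tr_idx = np.where(line_is_train)[0]
    mean_diag_g = float(np.diag(data.G.values)[tr_idx].mean()) if data.G is not None else None
    mean_diag_a = float(np.diag(data.A.values)[tr_idx].mean()) if data.A is not None else None
    msx = None
    if is_marker_model:
        msx = float(np.var(data.X[line_is_train], axis=0, ddof=1).sum())
    scale_kind = "bgblup_pedigree" if (model == "bgblup" and use_pedigree) else model
    scales = build_scale_parameters(
        y_t, scale_kind, priors, mean_diag_g=mean_diag_g,
        mean_diag_a=mean_diag_a if use_pedigree else None, msx=msx,
    )
    df = priors.df

    # --- working state ---------------------------------------------------
    beta0 = float(y_t.mean())
    r = y_t - beta0
    s2e = fixed.get("sigma2_e", max(scales.S0 / (df + 2.0), _VAR_FLOOR))

    def block(B):
        Bo = np.asfortranarray(B[obs_line_t])
        return Bo, (Bo**2).sum(axis=0), np.zeros(B.shape[1])

    if B_G is not None:
        BGo, colsq_g, b_g = block(B_G)
        s2g = fixed.get("sigma2_g", max(scales.Sg / (df + 2.0), _VAR_FLOOR))
    if B_A is not None:
        BAo, colsq_a, b_a = block(B_A)
        Sa = scales.Sa
        if Sa is None:  # preset scales without a pedigree entry
            Sa = scales.S0 * 0.25
        s2a = fixed.get("sigma2_a", max(Sa / (df + 2.0), _VAR_FLOOR))
    if is_marker_model:
        Xo = np.asfortranarray(Xc[obs_line_t])
        colsq_x = (Xo**2).sum(axis=0)
        p = Xo.shape[1]
        beta = np.zeros(p)
        if model == "lasso":
            if priors.lasso_fixed_lambda2 is not None:
                lam2 = float(priors.lasso_fixed_lambda2)
            else:
                lam2 = priors.lasso_shape / scales.lasso_rate
            sigma_j2 = np.full(p, 2.0 / lam2)
        else:
            s2b = fixed.get("sigma2_b", max(scales.Sb / (df + 2.0), _VAR_FLOOR))
            a_pi = priors.bayesc_p0 * priors.bayesc_pi0
            b_pi = priors.bayesc_p0 * (1.0 - priors.bayesc_pi0)
            pi = priors.bayesc_pi0
            gamma_ind = np.ones(p, dtype=np.int64)

    # a factor with a single level is indistinguishable from the intercept
    # and would only inflate the h2 denominator with a prior-dominated
    # variance draw, so such factors are dropped from the model
    use_exp = data.env is not None and len(data.env.experiment_levels) >= 2
    use_yr = data.env is not None and len(data.env.year_levels) >= 2
    has_env = use_exp or use_yr
    if has_env:
        S_env = scales.S_env if scales.S_env is not None else scales.S0 * 0.25
    if use_exp:
        exp_codes = data.env.experiment_codes[obs_mask]
        nL_exp = len(data.env.experiment_levels)
        counts_exp = np.bincount(exp_codes, minlength=nL_exp).astype(float)
        eff_exp = np.zeros(nL_exp)
        s2_alpha = fixed.get("sigma2_alpha", max(S_env / (df + 2.0), _VAR_FLOOR))
    if use_yr:
        yr_codes = data.env.year_codes[obs_mask]
        nL_yr = len(data.env.year_levels)
        counts_yr = np.bincount(yr_codes, minlength=nL_yr).astype(float)
        eff_yr = np.zeros(nL_yr)
        s2_gamma = fixed.get("sigma2_gamma", max(S_env / (df + 2.0), _VAR_FLOOR))

    # --- storage ---------------------------------------------------------
    n_stored = mcmc.n_stored
    store = {
        "beta0": np.empty(n_stored),
        "sigma2_e": np.empty(n_stored),
        "u": np.empty((n_stored, n_lines)),
    }
    if B_G is not None:
        store["sigma2_g"] = np.empty(n_stored)
    if B_A is not None:
        store["sigma2_a"] = np.empty(n_stored)
        store["v"] = np.empty((n_stored, n_lines))
    if is_marker_model:
        store["beta"] = np.empty((n_stored, p))
        if model == "lasso":
            store["lambda2"] = np.empty(n_stored)
        else:
            store["gamma"] = np.empty((n_stored, p), dtype=np.uint8)
            store["pi"] = np.empty(n_stored)
    if use_exp:
        store["alpha"] = np.empty((n_stored, nL_exp))
        store["sigma2_alpha"] = np.empty(n_stored)
    if use_yr:
        store["gamma_year"] = np.empty((n_stored, nL_yr))
        store["sigma2_gamma"] = np.empty(n_stored)

    k = 0
    for it in range(mcmc.n_iter):
        inv_s2e = 1.0 / s2e
        # intercept (flat prior)
        r += beta0
        beta0 = r.mean() + rng.standard_normal() * math.sqrt(s2e / n_obs)
        r -= beta0
        # environment factors
        if use_exp:
            _gibbs.update_factor(exp_codes, nL_exp, counts_exp, r, eff_exp, s2e, s2_alpha, rng)
            if "sigma2_alpha" not in fixed:
                s2_alpha = max(
                    _gibbs.draw_scaled_inv_chi2(rng, df + nL_exp, S_env + eff_exp @ eff_exp),
                    _VAR_FLOOR,
                )
        if use_yr:
            _gibbs.update_factor(yr_codes, nL_yr, counts_yr, r, eff_yr, s2e, s2_gamma, rng)
            if "sigma2_gamma" not in fixed:
                s2_gamma = max(
                    _gibbs.draw_scaled_inv_chi2(rng, df + nL_yr, S_env + eff_yr @ eff_yr),
                    _VAR_FLOOR,
                )
        # genomic kernel
        if B_G is not None:
            q = len(b_g)
            _gibbs.ridge_sweep(
                BGo, r, b_g, colsq_g, np.full(q, 1.0 / s2g), inv_s2e,
                rng.standard_normal(q),
            )
            if "sigma2_g" not in fixed:
                s2g = max(
                    _gibbs.draw_scaled_inv_chi2(rng, df + q, scales.Sg + b_g @ b_g),
                    _VAR_FLOOR,
                )
        # pedigree kernel
        if B_A is not None:
            q = len(b_a)
            _gibbs.ridge_sweep(
                BAo, r, b_a, colsq_a, np.full(q, 1.0 / s2a), inv_s2e,
                rng.standard_normal(q),
            )
            if "sigma2_a" not in fixed:
                s2a = max(
                    _gibbs.draw_scaled_inv_chi2(rng, df + q, Sa + b_a @ b_a),
                    _VAR_FLOOR,
                )
        # marker effects
        if is_marker_model:
            if model == "lasso":
                _gibbs.ridge_sweep(
                    Xo, r, beta, colsq_x, 1.0 / sigma_j2, inv_s2e,
                    rng.standard_normal(p),
                )
                absb = np.maximum(np.abs(beta), 1e-10)
                lam = math.sqrt(lam2)
                eta = rng.wald(lam / absb, lam2)  # 1 / sigma_j^2
                sigma_j2 = np.clip(1.0 / np.maximum(eta, 1e-12), 1e-12, 1e12)
                if priors.lasso_fixed_lambda2 is None:
                    lam2 = rng.gamma(
                        priors.lasso_shape + p,
                        1.0 / (scales.lasso_rate + sigma_j2.sum() / 2.0),
                    )
            else:
                _gibbs.bayesc_sweep(
                    Xo, r, beta, gamma_ind, colsq_x, inv_s2e, 1.0 / s2b, pi,
                    rng.standard_normal(p), rng.random(p),
                )
                n_in = int(gamma_ind.sum())
                if "sigma2_b" not in fixed:
                    ssb = float(beta @ beta)
                    s2b = max(
                        _gibbs.draw_scaled_inv_chi2(rng, df + n_in, scales.Sb + ssb),
                        _VAR_FLOOR,
                    )
                pi = rng.beta(a_pi + n_in, b_pi + p - n_in)
                pi = min(max(pi, 1e-8), 1.0 - 1e-8)
        # residual variance
        if "sigma2_e" not in fixed:
            s2e = max(
                _gibbs.draw_scaled_inv_chi2(rng, df + n_obs, scales.S0 + r @ r),
                _VAR_FLOOR,
            )
        # storage
        if it >= mcmc.burn_in and (it - mcmc.burn_in + 1) % mcmc.thin == 0:
            store["beta0"][k] = beta0
            store["sigma2_e"][k] = s2e
            if B_G is not None:
                store["sigma2_g"][k] = s2g
                store["u"][k] = B_G @ b_g
            elif is_marker_model:
                store["u"][k] = Xc @ beta
                store["beta"][k] = beta
                if model == "lasso":
                    store["lambda2"][k] = lam2
                else:
                    store["gamma"][k] = gamma_ind
                    store["pi"][k] = pi
            if B_A is not None:
                store["sigma2_a"][k] = s2a
                store["v"][k] = B_A @ b_a
            if use_exp:
                store["alpha"][k] = eff_exp
                store["sigma2_alpha"][k] = s2_alpha
            if use_yr:
                store["gamma_year"][k] = eff_yr
                store["sigma2_gamma"][k] = s2_gamma
            k += 1

    gebv = store["beta0"].mean() + store["u"].mean(axis=0)
    if "v" in store:
        gebv = gebv + store["v"].mean(axis=0)
    fit = PosteriorFit(
        model=model + ("_pedigree" if use_pedigree else ""),
        draws=store,
        line_ids=data.line_ids,
        gebv_mean=pd.Series(gebv, index=data.line_ids, name="gebv"),
        settings=mcmc,
        priors=priors,
        scales=scales,
        train_lines=sorted(data.line_ids[line_is_train]),
        marker_ids=data.marker_ids if is_marker_model else None,
        pip=(
            pd.Series(store["gamma"].mean(axis=0), index=data.marker_ids, name="pip")
            if model == "bayesc"
            else None
        ),
        x_center=x_center if is_marker_model else None,
    )
    return fit


def fit_bgblup(
    data: ModelData,
    priors: Optional[PriorConfig] = None,
    mcmc: Optional[MCMCSettings] = None,
    use_pedigree: bool = False,
    train_lines: Optional[Sequence[str]] = None,
    fixed_variances: Optional[Mapping[str, float]] = None,
) -> PosteriorFit:
    """Bayesian G-BLUP: genomic-kernel animal model, optional pedigree kernel."""
    return _fit_linear(data, "bgblup", priors, mcmc, use_pedigree, train_lines, fixed_variances)


def fit_bayesian_lasso(
    data: ModelData,
    priors: Optional[PriorConfig] = None,
    mcmc: Optional[MCMCSettings] = None,
    use_pedigree: bool = False,
    train_lines: Optional[Sequence[str]] = None,
    fixed_variances: Optional[Mapping[str, float]] = None,
) -> PosteriorFit:
    """Bayesian LASSO: double-exponential marker shrinkage via the
    normal-exponential mixture, Gamma hyperprior on lambda^2."""
    return _fit_linear(data, "lasso", priors, mcmc, use_pedigree, train_lines, fixed_variances)


def fit_bayes_c(
    data: ModelData,
    priors: Optional[PriorConfig] = None,
    mcmc: Optional[MCMCSettings] = None,
    use_pedigree: bool = False,
    train_lines: Optional[Sequence[str]] = None,
    fixed_variances: Optional[Mapping[str, float]] = None,
) -> PosteriorFit:
    """Bayes C: spike-and-slab marker prior with Beta-distributed inclusion
    probability; reports per-marker posterior inclusion probabilities."""
    return _fit_linear(data, "bayesc", priors, mcmc, use_pedigree, train_lines, fixed_variances)


def estimate_heritability(
    fit: PosteriorFit, include_pedigree: bool = False
) -> HeritabilityEstimate:
    """Genomic heritability h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 +
    sigma_alpha^2 + sigma_gamma^2), per draw, summarised by the posterior
    mean and the equal-tailed 95% credible interval.

    Environment variance draws are included when the fit has them; a fit
    without year/experiment terms contributes zero there.  With
    ``include_pedigree=True`` the pedigree variance sigma_a^2 enters the
    denominator as well (off by default).
    """
    d = fit.draws
    if "sigma2_g" not in d or "sigma2_e" not in d:
        raise ValueError("fit lacks genomic or residual variance draws")
    denom = d["sigma2_g"] + d["sigma2_e"]
    for key in ("sigma2_alpha", "sigma2_gamma"):
        if key in d:
            denom = denom + d[key]
    if include_pedigree:
        if "sigma2_a" not in d:
            raise ValueError("fit has no pedigree variance draws")
        denom = denom + d["sigma2_a"]
    h2 = d["sigma2_g"] / denom
    lo, hi = np.quantile(h2, [0.025, 0.975])
    return HeritabilityEstimate(float(h2.mean()), float(lo), float(hi))


def predict_gebv(
    fit: PosteriorFit,
    test_ids: Sequence[str],
    genotypes: Optional[GenotypeMatrix] = None,
) -> pd.Series:
    """Posterior-mean GEBVs for the requested lines.

    Lines that were part of the fit (including phenotype-masked test lines)
    are read from the jointly sampled posterior.  For marker models, new
    lines absent from the fit may be predicted from their dosages as
    X_new . posterior-mean effects (markers must match the training set).
    """
    known = set(fit.line_ids)
    missing = [t for t in test_ids if t not in known]
    if not missing:
        return fit.gebv_mean.loc[list(test_ids)]
    if genotypes is None or fit.marker_ids is None:
        raise KeyError(
            f"line {missing[0]!r} was not in the fitted data; marker models can "
            "predict new lines when their genotypes are provided"
        )
    if "v" in fit.draws:
        raise KeyError(
            "pedigree-augmented fits cannot extrapolate to lines outside the "
            "fitted relationship matrix"
        )
    if list(genotypes.marker_ids) != list(fit.marker_ids):
        raise ValueError("marker set of the new genotypes does not match the fit")
    gsub = genotypes.subset_lines(list(test_ids))
    Xn = gsub.dosages - fit.x_center
    vals = fit.draws["beta0"].mean() + Xn @ fit.draws["beta"].mean(axis=0)
    return pd.Series(vals, index=list(test_ids), name="gebv")
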