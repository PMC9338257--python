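"""Prediction-accuracy evaluation: k-fold cross-validation, forward-in-time
prediction, and per-family prediction with relatedness-restricted training
sets.  Accuracy is the Pearson correlation between GEBVs and line-level
phenotypes (the mean of a line's observations when it has several).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bart import BARTConfig, fit_bart
from .linear_bayes import (
    MCMCSettings,
    ModelData,
    PriorConfig,
    fit_bayes_c,
    fit_bayesian_lasso,
    fit_bgblup,
)
from .relatedness import RelationshipMatrix, select_related_training

__all__ = [
    "ModelSpec",
    "FoldAssignment",
    "ScenarioResult",
    "pearson_accuracy",
    "make_kfold",
    "fit_model",
    "run_scenario1",
    "run_scenario2",
    "run_scenario3",
]

_MODELS = ("bgblup", "lasso", "bayesc", "bart")


@dataclass(frozen=True)
class ModelSpec:
    """Which predictive model to run, and whether to add the pedigree kernel."""

    model: str = "bgblup"
    use_pedigree: bool = False
    bart: Optional[BARTConfig] = None

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.model == "bart" and self.use_pedigree:
            raise ValueError("the BART model has no pedigree variant")

    @property
    def tag(self) -> str:
        return self.model + ("+pedigree" if self.use_pedigree else "")


@dataclass
class FoldAssignment:
    """Partition of line ids into k folds (sizes differing by at most 1)."""

    assignment: Dict[str, int]
    k: int
    seed: int

    def __post_init__(self) -> None:
        folds = np.array(sorted(self.assignment.values()))
        if folds.min() < 1 or folds.max() > self.k:
            raise ValueError("fold indices must lie in 1..k")
        sizes = np.bincount(folds)[1:]
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes differ by more than 1")

    def fold(self, i: int) -> List[str]:
        return sorted(l for l, f in self.assignment.items() if f == i)

    def sizes(self) -> List[int]:
        folds = [f for f in self.assignment.values()]
        return [folds.count(i) for i in range(1, self.k + 1)]


@dataclass
class ScenarioResult:
    """Per-unit (fold or family) accuracies with the cross-unit summary."""

    table: pd.DataFrame  # columns: unit, n_train, n_test, accuracy, skipped
    model: str
    scenario: str

    @property
    def accuracies(self) -> np.ndarray:
        t = self.table
        return t.loc[~t["skipped"], "accuracy"].to_numpy(dtype=float)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def se(self) -> float:
        """Standard error over units: sample SD / sqrt(number of units)."""
        a = self.accuracies
        if len(a) < 2:
            return float("nan")
        return float(a.std(ddof=1) / math.sqrt(len(a)))


def pearson_accuracy(gebv: np.ndarray, phenotype: np.ndarray) -> float:
    """Pearson correlation between GEBVs and phenotypes."""
    g = np.asarray(gebv, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if g.shape != y.shape or g.ndim != 1:
        raise ValueError("gebv and phenotype must be 1-D of equal length")
    if len(g) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(g) == 0 or np.ptp(y) == 0:
        raise ValueError("accuracy undefined: an input vector is constant")
    return float(stats.pearsonr(g, y).statistic)


def make_kfold(ids: Sequence[str], k: int, seed: int) -> FoldAssignment:
    """Uniformly random near-equal partition of ids into k folds.

    Ids are sorted lexicographically before the seeded shuffle, so the
    partition depends only on the id set and the seed, not on input order.
    The first ``n mod k`` folds receive the remainder line each.
    """
    ids = sorted(map(str, ids))
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of ids ({n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, rem = divmod(n, k)
    assignment: Dict[str, int] = {}
    start = 0
    for f in range(1, k + 1):
        size = base + (1 if f <= rem else 0)
        for idx in perm[start : start + size]:
            assignment[ids[idx]] = f
        start += size
    return FoldAssignment(assignment=assignment, k=k, seed=seed)


def fit_model(
    data: ModelData,
    spec: ModelSpec,
    priors: Optional[PriorConfig] = None,
    mcmc: Optional[MCMCSettings] = None,
    train_lines: Optional[Sequence[str]] = None,
):
    """Dispatch one model fit; returns an object exposing ``gebv_mean``."""
    if spec.model == "bgblup":
        return fit_bgblup(data, priors, mcmc, spec.use_pedigree, train_lines)
    if spec.model == "lasso":
        return fit_bayesian_lasso(data, priors, mcmc, spec.use_pedigree, train_lines)
    if spec.model == "bayesc":
        return fit_bayes_c(data, priors, mcmc, spec.use_pedigree, train_lines)
    return fit_bart(data, spec.bart, mcmc, train_lines)


def _line_phenotype_means(data: ModelData) -> pd.Series:
    df = pd.DataFrame({"line": data.line_ids[data.obs_line], "y": data.y})
    return df.groupby("line")["y"].mean()


def run_scenario1(
    data: ModelData,
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
    mcmc: Optional[MCMCSettings] = None,
    priors: Optional[PriorConfig] = None,
    gebv_fn: Optional[Callable[[Sequence[str], Sequence[str]], pd.Series]] = None,
) -> ScenarioResult:
    """Random k-fold cross-validation: each fold is held out in turn as the
    test population, the model is refit on the complement, and the fold's
    accuracy is the Pearson correlation between held-out GEBVs and line
    phenotypes.  ``gebv_fn(train, test) -> Series`` replaces the model fit
    when supplied (oracle testing)."""
    line_means = _line_phenotype_means(data)
    ids = sorted(line_means.index)
    folds = make_kfold(ids, k, seed)
    rows = []
    for f in range(1, k + 1):
        test = folds.fold(f)
        train = sorted(set(ids) - set(test))
        try:
            if gebv_fn is not None:
                gebv = gebv_fn(train, test)
            else:
                fit = fit_model(data, spec, priors, mcmc, train_lines=train)
                gebv = fit.gebv_mean
            acc = pearson_accuracy(
                gebv.loc[test].to_numpy(), line_means.loc[test].to_numpy()
            )
        except Exception as e:
            raise RuntimeError(f"model failed in fold {f}: {e}") from e
        rows.append((f"fold{f}", len(train), len(test), acc, False))
    table = pd.DataFrame(
        rows, columns=["unit", "n_train", "n_test", "accuracy", "skipped"]
    )
    return ScenarioResult(table=table, model=spec.tag, scenario="scenario1")


def _line_latest_year(data: ModelData) -> pd.Series:
    if data.env is None:
        raise ValueError("scenario 2/3 need year labels in the data")
    years = np.asarray(data.env.year_levels, dtype=object)[data.env.year_codes]
    df = pd.DataFrame({"line": data.line_ids[data.obs_line], "year": years})
    return df.groupby("line")["year"].max()


def run_scenario2(
    data: ModelData,
    spec: ModelSpec,
    cutoff_year: str,
    mcmc: Optional[MCMCSettings] = None,
    priors: Optional[PriorConfig] = None,
    gebv_fn: Optional[Callable[[Sequence[str], Sequence[str]], pd.Series]] = None,
) -> ScenarioResult:
    """Forward-in-time prediction: lines from seasons before ``cutoff_year``
    train the model; lines whose latest season equals the cutoff are the
    test population."""
    cutoff = str(cutoff_year)
    line_year = _line_latest_year(data)
    train = sorted(line_year.index[line_year < cutoff])
    test = sorted(line_year.index[line_year == cutoff])
    if not train or not test:
        raise ValueError(
            f"degenerate year split at cutoff {cutoff!r}: "
            f"{len(train)} training / {len(test)} test lines"
        )
    line_means = _line_phenotype_means(data)
    if gebv_fn is not None:
        gebv = gebv_fn(train, test)
    else:
        fit = fit_model(data, spec, priors, mcmc, train_lines=train)
        gebv = fit.gebv_mean
    acc = pearson_accuracy(gebv.loc[test].to_numpy(), line_means.loc[test].to_numpy())
    table = pd.DataFrame(
        [(cutoff, len(train), len(test), acc, False)],
        columns=["unit", "n_train", "n_test", "accuracy", "skipped"],
    )
    return ScenarioResult(table=table, model=spec.tag, scenario="scenario2")


def run_scenario3(
    data: ModelData,
    spec: ModelSpec,
    families: Mapping[str, Sequence[str]],
    train_ids: Sequence[str],
    a: Optional[RelationshipMatrix] = None,
    threshold: Optional[float] = None,
    mcmc: Optional[MCMCSettings] = None,
    priors: Optional[PriorConfig] = None,
    gebv_fn: Optional[Callable[[Sequence[str], Sequence[str]], pd.Series]] = None,
) -> ScenarioResult:
    """Per-family prediction: each biparental family is a separate test
    population.  The training set is either ``train_ids`` as given
    (``threshold=None``) or its subset whose maximum pedigree relationship
    with the family reaches ``threshold``.  Families whose training subset
    comes up empty (or with fewer than 3 phenotyped test lines) are marked
    skipped, never silently dropped."""
    if threshold is not None and a is None:
        raise ValueError("a pedigree relationship matrix is needed for thresholding")
    line_means = _line_phenotype_means(data)
    rows = []
    for fam in sorted(families):
        test = sorted(set(families[fam]) & set(line_means.index))
        if threshold is None:
            train = sorted(set(train_ids) - set(test))
        else:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                train = select_related_training(
                    sorted(set(train_ids) - set(test)), test, a, threshold
                )
        if len(test) < 3 or not train:
            rows.append((fam, len(train), len(test), np.nan, True))
            continue
        try:
            if gebv_fn is not None:
                gebv = gebv_fn(train, test)
            else:
                fit = fit_model(data, spec, priors, mcmc, train_lines=train)
                gebv = fit.gebv_mean
            acc = pearson_accuracy(
                gebv.loc[test].to_numpy(), line_means.loc[test].to_numpy()
            )
        except Exception as e:
            raise RuntimeError(f"model failed for family {fam!r}: {e}") from e
        rows.append((fam, len(train), len(test), acc, False))
    table = pd.DataFrame(
        rows, columns=["unit", "n_train", "n_test", "accuracy", "skipped"]
    )
    return ScenarioResult(table=table, model=spec.tag, scenario="scenario3")
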