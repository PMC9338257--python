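"""Synthetic breeding-program generator.

Emulates the structure of an inbred-line breeding panel: founders drawn
from per-marker allele frequencies, biparental F1 crosses advanced by
selfing (single-seed descent) to around the F4 generation, families
assigned to year cohorts with experiments nested within years, and
line-level phenotypes composed of an additive genetic value plus year,
experiment and residual components scaled to hit configured variance
shares exactly.

Loci are transmitted independently (no recombination map): family
structure alone induces the genomic/pedigree correlation the prediction
models exploit.  Mendelian sampling is performed on explicit haplotypes,
so generated genotypes are always consistent with the recorded pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data_io import EnvironmentDesign, GenotypeMatrix, PedigreeTable, PhenotypeTable

__all__ = [
    "TraitConfig",
    "SimConfig",
    "SimulatedStudy",
    "simulate_breeding_program",
    "simulate_phenotypes",
    "simulate_study",
]


@dataclass
class TraitConfig:
    """Architecture of one simulated trait.

    h2 is the realised genomic variance share; year_share and
    experiment_share are the realised environmental shares (the residual
    takes the remainder).  Effects are drawn N(0, 1) at ``n_qtl`` marker
    positions and rescaled so the shares are met exactly on the generated
    data.
    """

    n_qtl: int = 200
    h2: float = 0.5
    year_share: float = 0.10
    experiment_share: float = 0.05
    mean: float = 0.0
    epistatic_pairs: int = 0  # multiplicative marker-pair terms (non-additive test traits)

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")
        shares = self.h2 + self.year_share + self.experiment_share
        if shares >= 1.0:
            raise ValueError("variance shares must sum to < 1")
        if self.n_qtl == 0 and self.epistatic_pairs == 0 and self.h2 > 0:
            raise ValueError("h2 > 0 is unreachable with zero QTL")


@dataclass
class SimConfig:
    """Layout of the simulated breeding program.

    Defaults are a desk-scale rendition of a multi-year breeding panel:
    600 lines in 30 biparental families of 20 offspring at the F4
    generation, 2000 markers on 26 chromosomes, 3 year cohorts with 2
    experiments each.
    """

    n_founders: int = 40
    n_families: int = 30
    offspring_per_family: int = 20
    selfing_generations: int = 3  # F1 selfed 3x -> lines at F4
    n_markers: int = 2000
    n_chromosomes: int = 26
    allele_freq_range: Tuple[float, float] = (0.1, 0.9)
    n_years: int = 3
    experiments_per_year: int = 2
    start_year: int = 2015
    traits: Dict[str, TraitConfig] = field(default_factory=lambda: {"trait": TraitConfig()})
    crosses: Optional[List[Tuple[int, int]]] = None  # explicit founder-index pairs
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_founders", "n_families", "offspring_per_family", "n_markers",
            "n_chromosomes", "n_years", "experiments_per_year",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")
        max_pairs = self.n_founders * (self.n_founders - 1) // 2
        n_crosses = self.n_families if self.crosses is None else len(self.crosses)
        if n_crosses > max_pairs:
            raise ValueError(
                f"cannot lay out {n_crosses} distinct biparental crosses from "
                f"{self.n_founders} founders"
            )


@dataclass
class SimulatedStudy:
    """A complete synthetic data set plus the generating truth."""

    config: SimConfig
    genotypes: GenotypeMatrix
    pedigree: PedigreeTable
    phenotypes: Optional[PhenotypeTable]
    env: Optional[EnvironmentDesign]
    families: Dict[str, List[str]]  # family id -> line ids
    line_meta: pd.DataFrame  # line_id, family, year, experiment
    truth: Dict[str, dict] = field(default_factory=dict)
    founder_freqs: Optional[np.ndarray] = None


def _gamete(hap1: np.ndarray, hap2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    pick = rng.integers(0, 2, size=hap1.shape[0]).astype(bool)
    return np.where(pick, hap1, hap2)


def simulate_breeding_program(
    config: Optional[SimConfig] = None, seed: Optional[int] = None
) -> SimulatedStudy:
    """Gene-drop genotypes and a pedigree for the configured program.

    Founder haplotypes are Bernoulli(p_j) draws; each family is the selfed
    progeny of one F1 plant, every offspring line descending through its own
    single-seed chain to the configured generation.  The pedigree records
    founders, F1s, intermediate selfing generations, and the lines.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = config.n_markers
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, size=p)

    founder_ids = [f"P{i+1:03d}" for i in range(config.n_founders)]
    founders = {
        fid: (
            (rng.random(p) < freqs).astype(np.float64),
            (rng.random(p) < freqs).astype(np.float64),
        )
        for fid in founder_ids
    }

    if config.crosses is not None:
        crosses = list(config.crosses)
    else:
        # random distinct parent pairs; founders may appear in several
        # crosses, producing half-sib families as in a real program
        seen = set()
        crosses = []
        while len(crosses) < config.n_families:
            i, j = rng.choice(config.n_founders, size=2, replace=False)
            key = (min(i, j), max(i, j))
            if key not in seen:
                seen.add(key)
                crosses.append((int(i), int(j)))

    ped_rows: List[Tuple[str, Optional[str], Optional[str]]] = [
        (fid, None, None) for fid in founder_ids
    ]
    fam_ids = [f"FAM{k+1:03d}" for k in range(len(crosses))]
    families: Dict[str, List[str]] = {}
    line_rows = []
    dosages = []
    line_ids = []
    years = [str(config.start_year + t) for t in range(config.n_years)]
    fam_year = {fam: years[k % config.n_years] for k, fam in enumerate(fam_ids)}

    for fam, (i, j) in zip(fam_ids, crosses):
        sire, dam = founder_ids[i], founder_ids[j]
        f1 = (_gamete(*founders[sire], rng), _gamete(*founders[dam], rng))
        f1_id = f"{fam}_F1"
        ped_rows.append((f1_id, sire, dam))
        families[fam] = []
        year = fam_year[fam]
        for o in range(config.offspring_per_family):
            lid = f"{fam}_L{o+1:02d}"
            if config.selfing_generations == 0:
                # each offspring is its own F1 plant from the same cross
                genome = (_gamete(*founders[sire], rng), _gamete(*founders[dam], rng))
                ped_rows.append((lid, sire, dam))
            else:
                parent_id = f1_id
                genome = f1
                for g in range(config.selfing_generations):
                    child = (_gamete(*genome, rng), _gamete(*genome, rng))
                    child_id = (
                        lid if g == config.selfing_generations - 1 else f"{lid}_S{g+2}"
                    )
                    ped_rows.append((child_id, parent_id, parent_id))
                    parent_id = child_id
                    genome = child
            exp = f"{year}_E{int(rng.integers(config.experiments_per_year)) + 1}"
            families[fam].append(lid)
            line_ids.append(lid)
            dosages.append(genome[0] + genome[1])
            line_rows.append((lid, fam, year, exp))

    marker_ids = np.array([f"M{j+1:05d}" for j in range(p)], dtype=object)
    chrom = np.array([f"chr{(j % config.n_chromosomes) + 1}" for j in range(p)])
    markers = pd.DataFrame(
        {"chromosome": chrom, "position": np.arange(p) * 50_000}, index=marker_ids
    )
    geno = GenotypeMatrix(
        np.asarray(line_ids, dtype=object), marker_ids, np.vstack(dosages), markers=markers
    )
    meta = pd.DataFrame(line_rows, columns=["line_id", "family", "year", "experiment"])
    return SimulatedStudy(
        config=config,
        genotypes=geno,
        pedigree=PedigreeTable(ped_rows),
        phenotypes=None,
        env=None,
        families=families,
        line_meta=meta,
        founder_freqs=freqs,
    )


def _scaled(x: np.ndarray, target_var: float) -> np.ndarray:
    """Centre and rescale so the realised (population) variance is exact."""
    xc = x - x.mean()
    sd = xc.std()
    if sd == 0:
        if target_var > 0:
            raise ValueError("cannot scale a constant component to positive variance")
        return xc
    return xc * np.sqrt(target_var) / sd


def simulate_phenotypes(
    study: SimulatedStudy,
    traits: Optional[Dict[str, TraitConfig]] = None,
    seed: Optional[int] = None,
) -> PhenotypeTable:
    """Generate line-level phenotypes mirroring the analysis model:
    y = mean + additive genetic value + year effect + experiment effect +
    residual, with each component rescaled so the realised variance shares
    equal the configured ones (total variance 1).  The truth (QTL positions,
    scaled effects, true breeding values, shares) is stored in
    ``study.truth`` per trait.
    """
    traits = traits or study.config.traits
    rng = np.random.default_rng(
        (study.config.seed + 1_000_003) if seed is None else seed
    )
    X = study.genotypes.dosages
    meta = study.line_meta
    year_lab = meta["year"].to_numpy()
    exp_lab = meta["experiment"].to_numpy()
    out = meta[["line_id", "year", "experiment"]].copy()
    for name, tc in traits.items():
        year_share = tc.year_share if len(set(year_lab)) > 1 else 0.0
        exp_share = tc.experiment_share if len(set(exp_lab)) > 1 else 0.0
        resid_share = 1.0 - tc.h2 - year_share - exp_share
        if tc.n_qtl > X.shape[1]:
            raise ValueError("n_qtl exceeds marker count")
        qtl = np.sort(rng.choice(X.shape[1], size=tc.n_qtl, replace=False))
        effects = rng.standard_normal(tc.n_qtl)
        g_raw = X[:, qtl] @ effects
        if tc.epistatic_pairs:
            pairs = rng.choice(X.shape[1], size=(tc.epistatic_pairs, 2), replace=False)
            for a, b in pairs:
                g_raw = g_raw + rng.standard_normal() * X[:, a] * X[:, b]
        if tc.h2 > 0 and np.var(g_raw) == 0:
            raise ValueError("genetic values are constant; h2 target unreachable")
        g = _scaled(g_raw, tc.h2)
        yr_eff = dict(zip(sorted(set(year_lab)), rng.standard_normal(len(set(year_lab)))))
        ex_eff = dict(zip(sorted(set(exp_lab)), rng.standard_normal(len(set(exp_lab)))))
        ycomp = _scaled(np.array([yr_eff[v] for v in year_lab]), year_share)
        ecomp = _scaled(np.array([ex_eff[v] for v in exp_lab]), exp_share)
        resid = _scaled(rng.standard_normal(len(g)), resid_share)
        out[name] = tc.mean + g + ycomp + ecomp + resid
        study.truth[name] = {
            "qtl_idx": qtl,
            "qtl_effects": effects,
            "tbv": pd.Series(g, index=meta["line_id"].to_numpy(), name="tbv"),
            "shares": {
                "h2": tc.h2,
                "year": year_share,
                "experiment": exp_share,
                "residual": resid_share,
            },
        }
    pheno = PhenotypeTable(out)
    study.phenotypes = pheno
    study.env = EnvironmentDesign.from_phenotypes(pheno)
    return pheno


def simulate_study(
    config: Optional[SimConfig] = None, seed: Optional[int] = None
) -> SimulatedStudy:
    """Convenience wrapper: gene-drop the program and phenotype it."""
    study = simulate_breeding_program(config, seed=seed)
    simulate_phenotypes(study, seed=None if seed is None else seed + 1_000_003)
    return study
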