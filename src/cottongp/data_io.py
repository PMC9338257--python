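"""Input handling for genomic prediction: genotypes, pedigree, phenotypes.

Genotype tables are delimited text with breeding lines in rows and biallelic
SNP markers in columns, either as diploid calls (``AA``/``AB``/``BB``) or as
B-allele dosages (0/1/2).  Internally everything is held as dosage of the
B allele; missing calls are ``NaN`` in the dosage array and exposed through
:attr:`GenotypeMatrix.missing_mask`.

Pedigrees are three-column tables (individual, parent1, parent2); unknown
parents may be blank, ``NA`` or ``0``.  Phenotypes are line-level adjusted
trait values with a year and an experiment label per observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PedigreeTable",
    "PhenotypeTable",
    "EnvironmentDesign",
    "FilterReport",
    "read_genotypes",
    "read_pedigree",
    "read_phenotypes",
    "filter_markers",
    "impute_missing",
    "dosages_to_calls",
]

_CALL_TO_DOSAGE = {"AA": 0.0, "AB": 1.0, "BA": 1.0, "BB": 2.0}
_DOSAGE_TO_CALL = {0: "AA", 1: "AB", 2: "BB"}
_MISSING_TOKENS = {"", "NA", "NAN", "N/A", "--", ".", "./.", "MISSING"}


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with marker metadata.

    Parameters
    ----------
    line_ids
        Ordered unique line identifiers (length n).
    marker_ids
        Ordered unique marker identifiers (length p).
    dosages
        ``(n, p)`` float array with values in {0, 1, 2} or NaN for missing.
    markers
        Optional marker map with columns ``chromosome`` and ``position``
        indexed by marker id.
    coding_note
        Which allele the dosage counts (default: the B allele of an AA/AB/BB
        call, so AA -> 0, AB -> 1, BB -> 2).
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray
    markers: Optional[pd.DataFrame] = None
    coding_note: str = "dosage of the B allele (AA=0, AB=1, BB=2)"
    filter_report: Optional["FilterReport"] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if n < 1 or p < 1:
            raise ValueError("genotype matrix must have at least one line and one marker")
        if len(self.line_ids) != n or len(self.marker_ids) != p:
            raise ValueError("id lengths do not match dosage matrix shape")
        for name, ids in (("line", self.line_ids), ("marker", self.marker_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids in genotype table")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            # imputed matrices may carry fractional dosages; only freshly
            # validated integer matrices pass through here
            bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))]
            if not np.all((bad >= 0) & (bad <= 2)):
                raise ValueError("dosages must lie in [0, 2]")

    # -- basic accessors -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, p) mask, True where the call is missing."""
        return np.isnan(self.dosages)

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        return 1.0 - self.missing_mask.mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Counted (B) allele frequency per marker, from non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker."""
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids)

    def subset_lines(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {l: i for i, l in enumerate(self.line_ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return GenotypeMatrix(
            np.asarray(ids, dtype=object), self.marker_ids, self.dosages[idx],
            markers=self.markers, coding_note=self.coding_note,
        )


@dataclass
class FilterReport:
    n_input: int
    n_removed_call_rate: int
    n_removed_maf: int
    n_kept: int


@dataclass
class PedigreeTable:
    """Three-column pedigree: (individual, parent1, parent2), founders first.

    Unknown parents are ``None``.  The table is validated to be acyclic and
    stored in topological order (every parent precedes its offspring).
    """

    records: List[Tuple[str, Optional[str], Optional[str]]]

    def __post_init__(self) -> None:
        if isinstance(self.records, pd.DataFrame):
            self.records = [
                (str(r[0]),
                 None if pd.isna(r[1]) else str(r[1]),
                 None if pd.isna(r[2]) else str(r[2]))
                for r in self.records.itertuples(index=False)
            ]
        declared = {r[0] for r in self.records}
        if len(declared) != len(self.records):
            seen: set = set()
            dup = next(r[0] for r in self.records if r[0] in seen or seen.add(r[0]))
            raise ValueError(f"duplicate individual {dup!r} in pedigree")
        # auto-create founder rows for referenced but undeclared parents
        extra = []
        for _, p1, p2 in self.records:
            for p in (p1, p2):
                if p is not None and p not in declared:
                    warnings.warn(
                        f"parent {p!r} not declared as an individual; "
                        "treated as an unknown-parent founder",
                        stacklevel=2,
                    )
                    declared.add(p)
                    extra.append((p, None, None))
        self.records = extra + list(self.records)
        g = nx.DiGraph()
        g.add_nodes_from(r[0] for r in self.records)
        for ind, p1, p2 in self.records:
            for p in (p1, p2):
                if p is not None:
                    g.add_edge(p, ind)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise ValueError(f"pedigree contains a cycle: {path}")
        order = list(nx.lexicographical_topological_sort(g))
        by_id = {r[0]: r for r in self.records}
        self.records = [by_id[i] for i in order]

    @property
    def individuals(self) -> List[str]:
        return [r[0] for r in self.records]

    @property
    def parents(self) -> Dict[str, Tuple[Optional[str], Optional[str]]]:
        return {r[0]: (r[1], r[2]) for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["individual", "parent1", "parent2"])


@dataclass
class PhenotypeTable:
    """Line-level adjusted trait values with year and experiment labels.

    ``data`` must contain columns ``line_id``, ``year``, ``experiment`` plus
    one column per trait.  Each (line, year, experiment) combination may
    appear at most once.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"line_id", "year", "experiment"}
        missing = req - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        key = self.data[["line_id", "year", "experiment"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (line, year, experiment) row: {dup}")
        for t in self.traits:
            v = pd.to_numeric(self.data[t], errors="coerce")
            if np.isinf(v.to_numpy(dtype=float, na_value=np.nan)).any():
                raise ValueError(f"non-finite values in trait {t!r}")
        self.data = self.data.reset_index(drop=True)

    @property
    def traits(self) -> List[str]:
        return [c for c in self.data.columns if c not in ("line_id", "year", "experiment")]

    @property
    def line_ids(self) -> np.ndarray:
        return self.data["line_id"].to_numpy(dtype=object)

    def line_means(self, trait: str) -> pd.Series:
        """Per-line mean of the trait over its observations."""
        return self.data.groupby("line_id")[trait].mean()


@dataclass
class EnvironmentDesign:
    """Incidence of observations onto experiment and year levels."""

    experiment_levels: List[str]
    year_levels: List[str]
    experiment_codes: np.ndarray
    year_codes: np.ndarray

    def __post_init__(self) -> None:
        if not self.experiment_levels or not self.year_levels:
            raise ValueError("experiment and year level sets must be non-empty")
        if len(self.experiment_codes) != len(self.year_codes):
            raise ValueError("incidence vectors differ in length")
        for codes, levels, name in (
            (self.experiment_codes, self.experiment_levels, "experiment"),
            (self.year_codes, self.year_levels, "year"),
        ):
            codes = np.asarray(codes)
            if codes.min(initial=0) < 0 or codes.max(initial=0) >= len(levels):
                raise ValueError(f"{name} codes out of range")

    @classmethod
    def from_phenotypes(cls, pheno: PhenotypeTable) -> "EnvironmentDesign":
        exp = pd.Categorical(pheno.data["experiment"].astype(str))
        yr = pd.Categorical(pheno.data["year"].astype(str))
        return cls(
            experiment_levels=list(exp.categories),
            year_levels=list(yr.categories),
            experiment_codes=np.asarray(exp.codes, dtype=int),
            year_codes=np.asarray(yr.codes, dtype=int),
        )


# ---------------------------------------------------------------------------
# readers


def _parse_call(tok: str, line_id: str, marker_id: str) -> float:
    t = tok.strip().upper()
    if t in _MISSING_TOKENS:
        return np.nan
    if t in _CALL_TO_DOSAGE:
        return _CALL_TO_DOSAGE[t]
    raise ValueError(
        f"unparseable genotype call {tok!r} at line {line_id!r}, marker {marker_id!r}"
    )


def read_genotypes(path, dialect: str = "calls") -> GenotypeMatrix:
    """Read a delimited genotype table (lines in rows, markers in columns).

    Parameters
    ----------
    path
        CSV/TSV file; first column holds line ids, header row marker ids.
    dialect
        ``"calls"`` for AA/AB/BB tokens, ``"dosage"`` for numeric 0/1/2.
    """
    if dialect not in ("calls", "dosage"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    line_ids = df.index.astype(str).to_numpy(dtype=object)
    marker_ids = df.columns.astype(str).to_numpy(dtype=object)
    if len(set(line_ids)) != len(line_ids):
        raise ValueError("duplicate line ids in genotype file")
    if len(set(marker_ids)) != len(marker_ids):
        raise ValueError("duplicate marker ids in genotype file")
    if dialect == "calls":
        dos = np.empty(df.shape, dtype=float)
        raw = df.to_numpy(dtype=object)
        for i in range(raw.shape[0]):
            for j in range(raw.shape[1]):
                tok = raw[i, j]
                if tok is None or (isinstance(tok, float) and np.isnan(tok)):
                    dos[i, j] = np.nan
                else:
                    dos[i, j] = _parse_call(str(tok), line_ids[i], marker_ids[j])
    else:
        num = df.apply(pd.to_numeric, errors="coerce")
        dos = num.to_numpy(dtype=float)
        bad = ~(np.isnan(dos) | np.isin(dos, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {df.iloc[i, j]!r} at line {line_ids[i]!r}, "
                f"marker {marker_ids[j]!r}"
            )
    return GenotypeMatrix(line_ids, marker_ids, dos)


def dosages_to_calls(dosages: np.ndarray) -> np.ndarray:
    """Inverse recoding of integer dosages to AA/AB/BB tokens (NaN -> 'NA')."""
    d = np.asarray(dosages, dtype=float)
    out = np.full(d.shape, "NA", dtype=object)
    for v, call in _DOSAGE_TO_CALL.items():
        out[d == v] = call
    return out


def read_pedigree(path) -> PedigreeTable:
    """Read a 3-column pedigree CSV (individual, parent1, parent2)."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 3:
        raise ValueError("pedigree file needs three columns: individual, parent1, parent2")
    recs = []
    for _, row in df.iterrows():
        ind = str(row.iloc[0]).strip()
        parents = []
        for tok in row.iloc[1:3]:
            t = "" if tok is None or (isinstance(tok, float) and np.isnan(tok)) else str(tok).strip()
            parents.append(None if t.upper() in _MISSING_TOKENS or t == "0" else t)
        recs.append((ind, parents[0], parents[1]))
    return PedigreeTable(recs)


def read_phenotypes(path, genotyped_lines: Optional[Sequence[str]] = None) -> PhenotypeTable:
    """Read the phenotype CSV; warn (not error) about lines without genotypes."""
    df = pd.read_csv(path)
    df["line_id"] = df["line_id"].astype(str)
    pt = PhenotypeTable(df)
    if genotyped_lines is not None:
        unknown = sorted(set(pt.line_ids) - set(map(str, genotyped_lines)))
        if unknown:
            warnings.warn(
                f"{len(unknown)} phenotyped lines have no genotype (e.g. {unknown[:3]})",
                stacklevel=2,
            )
    return pt


# ---------------------------------------------------------------------------
# marker QC


def filter_markers(
    g: GenotypeMatrix, min_call_rate: float = 0.85, min_maf: float = 0.025
) -> GenotypeMatrix:
    """Retain markers with call rate and MAF strictly above the thresholds.

    Defaults mirror routine SNP-chip QC for breeding panels: call rate above
    85% and minor-allele frequency above 2.5%, both read as strict
    inequalities.  MAF is computed on non-missing calls.  The returned matrix
    carries a :class:`FilterReport` in ``filter_report``.
    """
    for name, v in (("min_call_rate", min_call_rate), ("min_maf", min_maf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    cr = g.call_rate()
    maf = g.maf()
    ok_cr = cr > min_call_rate
    with np.errstate(invalid="ignore"):
        ok_maf = np.nan_to_num(maf, nan=-1.0) > min_maf
    keep = ok_cr & ok_maf
    if not keep.any():
        raise ValueError(
            "all markers removed by QC; review min_call_rate/min_maf thresholds"
        )
    out = GenotypeMatrix(
        g.line_ids,
        g.marker_ids[keep],
        g.dosages[:, keep],
        markers=None if g.markers is None else g.markers.loc[g.marker_ids[keep]],
        coding_note=g.coding_note,
    )
    out.filter_report = FilterReport(
        n_input=g.n_markers,
        n_removed_call_rate=int((~ok_cr).sum()),
        n_removed_maf=int((ok_cr & ~ok_maf).sum()),
        n_kept=int(keep.sum()),
    )
    return out


def impute_missing(g: GenotypeMatrix, rule: str = "marker_mean") -> GenotypeMatrix:
    """Fill missing calls per marker with its mean or modal dosage.

    ``marker_mean`` fills with the marker's mean dosage (continuous);
    ``marker_mode`` with the most frequent dosage (ties broken toward the
    lower dosage for determinism).  Observed cells are never changed.
    """
    if rule not in ("marker_mean", "marker_mode"):
        raise ValueError(f"unknown imputation rule {rule!r}")
    mask = g.missing_mask
    if not mask.any():
        return GenotypeMatrix(
            g.line_ids, g.marker_ids, g.dosages.copy(),
            markers=g.markers, coding_note=g.coding_note,
        )
    fully = mask.all(axis=0)
    if fully.any():
        bad = g.marker_ids[fully][0]
        raise ValueError(
            f"marker {bad!r} has no observed calls; run filter_markers first"
        )
    dos = g.dosages.copy()
    if rule == "marker_mean":
        fill = np.nanmean(dos, axis=0)
    else:
        fill = np.empty(g.n_markers)
        for j in range(g.n_markers):
            col = dos[:, j]
            col = col[~np.isnan(col)]
            counts = np.array([(col == v).sum() for v in (0.0, 1.0, 2.0)])
            fill[j] = float(np.argmax(counts))  # argmax keeps the lowest dosage on ties
    rows, cols = np.where(mask)
    dos[rows, cols] = fill[cols]
    return GenotypeMatrix(
        g.line_ids, g.marker_ids, dos, markers=g.markers, coding_note=g.coding_note
    )
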