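"""Genomic (G) and pedigree (A) relationship matrices.

The genomic relationship matrix follows VanRaden's Method 1,

    G_ik = (1/p) * sum_j (x_ij - 2 p_j)(x_kj - 2 p_j) / (2 p_j (1 - p_j)),

with x_ij the B-allele dosage (0/1/2), p_j the counted-allele frequency and
p the number of markers.  The numerator (pedigree) relationship matrix A is
built by the tabular method with ancestors truncated at a configurable
number of generations (default five).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix, PedigreeTable

__all__ = [
    "RelationshipMatrix",
    "compute_grm",
    "compute_nrm",
    "select_related_training",
    "pca_scores",
]


@dataclass
class RelationshipMatrix:
    """Symmetric line x line relationship matrix, genomic or pedigree."""

    ids: np.ndarray
    values: np.ndarray
    kind: str  # "genomic" | "pedigree"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in relationship matrix")
        if self.kind not in ("genomic", "pedigree"):
            raise ValueError(f"unknown kind {self.kind!r}")
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        if asym > 1e-10:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:.2e})")
        d = np.diag(self.values)
        if (d < 0).any():
            raise ValueError("negative diagonal entries")
        if self.kind == "pedigree" and ((d < 1 - 1e-8) | (d > 2 + 1e-8)).any():
            raise ValueError("pedigree diagonal entries must lie in [1, 2]")
        self._pos = {i: k for k, i in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def loc(self, rows: Sequence[str], cols: Optional[Sequence[str]] = None) -> np.ndarray:
        """Submatrix by id, in the order given."""
        cols = rows if cols is None else cols
        try:
            ri = np.array([self._pos[i] for i in rows], dtype=int)
            ci = np.array([self._pos[i] for i in cols], dtype=int)
        except KeyError as e:
            raise KeyError(f"id {e.args[0]!r} not in relationship matrix") from None
        return self.values[np.ix_(ri, ci)]

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        return RelationshipMatrix(np.asarray(ids, dtype=object), self.loc(ids), self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path, kind: str) -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.index.astype(str).to_numpy(object), df.to_numpy(float), kind)


def compute_grm(
    g: GenotypeMatrix, allele_freq: Optional[np.ndarray] = None
) -> RelationshipMatrix:
    """VanRaden Method-1 genomic relationship matrix.

    Parameters
    ----------
    g
        Complete (imputed) dosage matrix; every marker must be polymorphic.
    allele_freq
        Optional counted-allele frequencies to centre and scale by.  By
        default these are estimated from the data; supplying base-population
        (e.g. founder) frequencies instead references G to that population,
        which is the natural scale for comparison with a pedigree A matrix.
    """
    X = g.dosages
    if np.isnan(X).any():
        raise ValueError("missing dosages present; impute_missing first")
    p_j = X.mean(axis=0) / 2.0 if allele_freq is None else np.asarray(allele_freq, float)
    if p_j.shape != (g.n_markers,):
        raise ValueError("allele_freq length does not match marker count")
    mono = (p_j <= 0.0) | (p_j >= 1.0)
    if mono.any():
        raise ValueError(
            f"monomorphic marker {g.marker_ids[mono][0]!r} (allele frequency 0 or 1) "
            "would divide by zero; remove it with filter_markers"
        )
    Xc = X - 2.0 * p_j
    w = 1.0 / (2.0 * p_j * (1.0 - p_j))
    G = (Xc * w) @ Xc.T / g.n_markers
    G = (G + G.T) / 2.0
    return RelationshipMatrix(g.line_ids, G, kind="genomic")


def compute_nrm(
    ped: PedigreeTable,
    ids: Optional[Sequence[str]] = None,
    max_depth: int = 5,
) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Founders have A_ii = 1 and are mutually unrelated; for individual x with
    parents s and d, A_xi = 0.5 (A_si + A_di) and A_xx = 1 + 0.5 A_sd.
    Ancestors more than ``max_depth`` generations above any requested id are
    treated as founders (the pedigree is "traced back" max_depth
    generations).
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    parents = ped.parents
    targets = list(ped.individuals) if ids is None else list(ids)
    for t in targets:
        if t not in parents:
            raise KeyError(f"id {t!r} not in pedigree")
    # breadth-first ancestor closure with generation truncation
    depth = {t: 0 for t in targets}
    frontier = list(targets)
    while frontier:
        nxt = []
        for ind in frontier:
            if depth[ind] >= max_depth:
                continue
            for p in parents.get(ind, (None, None)):
                if p is None:
                    continue
                d = depth[ind] + 1
                if p not in depth or d < depth[p]:
                    depth[p] = d
                    nxt.append(p)
        frontier = nxt
    keep = set(depth)
    order = [i for i in ped.individuals if i in keep]
    pos = {i: k for k, i in enumerate(order)}
    m = len(order)
    A = np.zeros((m, m))
    for x in order:
        ix = pos[x]
        if depth[x] >= max_depth:
            s = d = None  # truncated: treated as a founder
        else:
            s, d = parents[x]
            s = s if (s in pos and pos[s] < ix) else None
            d = d if (d in pos and pos[d] < ix) else None
        row = np.zeros(ix)
        if s is not None:
            row += 0.5 * A[pos[s], :ix]
        if d is not None:
            row += 0.5 * A[pos[d], :ix]
        A[ix, :ix] = row
        A[:ix, ix] = row
        A[ix, ix] = 1.0 + (0.5 * A[pos[s], pos[d]] if s is not None and d is not None else 0.0)
    ti = np.array([pos[t] for t in targets], dtype=int)
    return RelationshipMatrix(
        np.asarray(targets, dtype=object), A[np.ix_(ti, ti)], kind="pedigree"
    )


def select_related_training(
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    a: RelationshipMatrix,
    threshold: float,
) -> List[str]:
    """Training lines whose maximum relationship with any test line >= threshold.

    The pairwise maximum (not mean) is used: relatedness classes such as
    half-sib (0.25) or first-cousin (0.125) are defined per pair of lines.
    Order of ``train_ids`` is preserved.  An empty result raises a warning
    but is returned as-is.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    block = a.loc(list(train_ids), list(test_ids))
    keep = block.max(axis=1) >= threshold
    out = [t for t, k in zip(train_ids, keep) if k]
    if not out:
        warnings.warn("no training lines reach the relatedness threshold", stacklevel=2)
    return out


def pca_scores(g: GenotypeMatrix, n_components: int) -> pd.DataFrame:
    """Principal-component scores of the column-centred dosage matrix.

    Returns a line x component DataFrame (columns ``PC1``..); per-component
    variances (non-increasing) are stored in ``.attrs["explained_variance"]``.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(g.n_lines, g.n_markers):
        raise ValueError("n_components exceeds min(n_lines, n_markers)")
    X = g.dosages
    if np.isnan(X).any():
        raise ValueError("missing dosages present; impute_missing first")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    df = pd.DataFrame(
        scores, index=g.line_ids, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    df.attrs["explained_variance"] = (s[:n_components] ** 2) / max(g.n_lines - 1, 1)
    return df
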