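"""Pairwise similarity/distance on band profiles, and principal coordinates.

Nei-Li similarity (the Dice coefficient on shared band presences),
S = 2a / (2a + b + c), is the standard similarity for dominant marker
profiles; its complement 1 - S feeds UPGMA clustering.  The modified
Rogers distance (MRD) treats each 0/1 profile as an allele-frequency
vector under the two-alleles-per-locus convention and reduces to
sqrt(Hamming / L), an L2 metric whose matrices are Euclidean-embeddable.
Principal coordinate analysis (Gower) double-centres the squared
distances, B = -1/2 J (D o D) J, and scales eigenvectors by the square
roots of the positive eigenvalues; negative eigenvalues are reported,
never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .band_data import BandMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "nei_li_similarity",
    "nei_li_similarity_matrix",
    "nei_li_distance_matrix",
    "modified_rogers_distance",
    "mrd_matrix",
    "euclidean_squared_matrix",
    "similarity_summary",
    "PcoaResult",
    "pcoa",
    "write_distance_tsv",
    "read_distance_tsv",
    "write_phylip",
]


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray = field(repr=False)
    metric: str = "custom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} vs {n} labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if np.any(self.values < -1e-12):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries, row-major (scipy condensed order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


# -- pairwise coefficients -------------------------------------------------

def _pairwise_complete_counts(X: np.ndarray):
    """a, b, c, d count matrices over pairwise-complete entries.

    X is (n, L) with NaN for missing; returns (n, n) matrices of shared
    presences (a), presences unique to the row sample (b), unique to the
    column sample (c) and shared absences (d).
    """
    P = np.nan_to_num(X, nan=0.0)            # presence indicator
    A = np.where(np.isnan(X), 0.0, 1.0 - np.nan_to_num(X, nan=0.0))  # absence
    a = P @ P.T
    b = P @ A.T
    c = A @ P.T
    d = A @ A.T
    return a, b, c, d


def nei_li_similarity(x, y) -> float:
    """Nei-Li (Dice) similarity 2a/(2a+b+c) of two band vectors.

    Pairwise-complete over missing entries.  If neither profile shows any
    band the similarity is defined as 1 (identical absence profiles) with
    a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("band vectors differ in length")
    ok = ~np.isnan(x) & ~np.isnan(y)
    a = float(np.sum((x == 1) & (y == 1) & ok))
    b = float(np.sum((x == 1) & (y == 0) & ok))
    c = float(np.sum((x == 0) & (y == 1) & ok))
    if a + b + c == 0:
        logger.warning("no band presences in either profile; similarity defined as 1")
        return 1.0
    return 2.0 * a / (2.0 * a + b + c)


def nei_li_similarity_matrix(m: BandMatrix) -> np.ndarray:
    """All-pairs Nei-Li similarity (vectorised, pairwise-complete)."""
    a, b, c, _ = _pairwise_complete_counts(m.values)
    denom = 2.0 * a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, 2.0 * a / np.where(denom > 0, denom, 1.0), 1.0)
    if np.any(denom == 0):
        logger.warning("sample pair(s) with no band presences; similarity set to 1")
    np.fill_diagonal(S, 1.0)
    return S


def nei_li_distance_matrix(m: BandMatrix) -> DistanceMatrix:
    """1 - Nei-Li similarity as a DistanceMatrix."""
    D = 1.0 - nei_li_similarity_matrix(m)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(m.samples), D, metric="nei_li_distance")


def modified_rogers_distance(x, y, L: int | None = None) -> float:
    """Modified Rogers distance between two 0/1 band profiles.

    Under the two-allele-per-locus convention each profile is the
    frequency vector (x_l, 1-x_l) per locus, and

        MRD = sqrt( sum_l [(x_l-y_l)^2 + ((1-x_l)-(1-y_l))^2] / (2L) )
            = sqrt( Hamming(x, y) / L ).

    ``L`` defaults to the number of pairwise-complete loci.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("band vectors differ in length")
    ok = ~np.isnan(x) & ~np.isnan(y)
    if L is None:
        L = int(ok.sum())
    if L == 0:
        raise ValueError("zero loci for MRD")
    ham = float(np.sum((x[ok] - y[ok]) ** 2))
    return float(np.sqrt(ham / L))


def mrd_matrix(m: BandMatrix) -> DistanceMatrix:
    """All-pairs modified Rogers distance."""
    X = m.values
    ok = ~np.isnan(X)
    P = np.nan_to_num(X, nan=0.0)
    # pairwise Hamming over complete entries: |x - y|^2 with missing zeroed
    both = ok.astype(float) @ ok.astype(float).T          # complete loci per pair
    cross = P @ (ok.astype(float) - P).T
    ham = cross + cross.T                                  # x(1-y) + (1-x)y
    if np.any(both == 0):
        raise ValueError("sample pair with zero pairwise-complete loci")
    D = np.sqrt(ham / both)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(m.samples), D, metric="mrd")


def euclidean_squared_matrix(m: BandMatrix) -> DistanceMatrix:
    """Euclidean distance on 0/1 profiles (sqrt of Hamming count).

    The squared entries are Hamming counts — the squared-distance scale
    used by molecular variance partitioning.
    """
    d = mrd_matrix(m)
    X = m.values
    ok = (~np.isnan(X)).astype(float)
    both = ok @ ok.T
    vals = d.values * np.sqrt(both)       # undo the 1/L normalisation
    return DistanceMatrix(d.labels, vals, metric="euclidean")


def similarity_summary(m: BandMatrix) -> tuple[float, float, float]:
    """(min, mean, max) Nei-Li similarity over all unordered sample pairs."""
    if m.n_samples < 2:
        raise ValueError("need at least two samples")
    S = nei_li_similarity_matrix(m)
    iu = np.triu_indices(m.n_samples, k=1)
    vals = S[iu]
    return float(vals.min()), float(vals.mean()), float(vals.max())


# -- principal coordinate analysis ----------------------------------------

@dataclass
class PcoaResult:
    """Eigenvalues (all, descending), coordinates on positive axes, and
    the per-axis proportion of (positive) variance."""

    eigenvalues: np.ndarray
    coordinates: pd.DataFrame
    proportion_explained: np.ndarray


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PcoaResult:
    """Classical (Gower) PCoA via double-centering.

    B = -1/2 J (D o D) J with J = I - 11'/n; coordinates are eigenvectors
    scaled by sqrt(eigenvalue) for positive eigenvalues.  Negative
    eigenvalues (non-Euclidean input) appear in ``eigenvalues`` but are
    excluded from the coordinate scaling.
    """
    n = d.n
    D2 = d.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        logger.warning("requested %d axes but only %d positive eigenvalues", n_axes, n_pos)
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes]) if n_axes else np.zeros((n, 0))
    total_pos = evals[pos].sum() if n_pos else 1.0
    prop = np.where(pos, evals / total_pos, 0.0)
    frame = pd.DataFrame(
        coords, index=d.labels, columns=[f"PCo{i + 1}" for i in range(n_axes)]
    )
    return PcoaResult(evals, frame, prop)


# -- serialisation ---------------------------------------------------------

def write_distance_tsv(d: DistanceMatrix, path) -> None:
    pd.DataFrame(d.values, index=d.labels, columns=d.labels).to_csv(path, sep="\t")


def read_distance_tsv(path, metric: str = "custom") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(float), metric=metric)


def write_phylip(d: DistanceMatrix, path) -> None:
    """Square PHYLIP distance format."""
    with open(path, "w") as fh:
        fh.write(f"{d.n}\n")
        for lab, row in zip(d.labels, d.values):
            fh.write(f"{lab:<10s} " + " ".join(f"{v:.6f}" for v in row) + "\n")
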