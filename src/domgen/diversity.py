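"""Polymorphism counts and genetic-diversity indices for dominant bands.

Per primer, per marker type, and overall, this module reports the total
number of bands (TNB), number of polymorphic bands (NPB), percentage of
polymorphic bands (PPB = 100 * NPB / TNB), Nei's gene diversity H and
Shannon's information index I.

For dominant data the allele frequencies behind H and I are not directly
observed: the band-absent phenotype is the recessive homozygote, so under
HWE the null-allele frequency is estimated as ``q = sqrt(1 - band_freq)``
(the classic square-root estimator), optionally with the Lynch-Milligan
small-sample bias correction.  Monomorphic loci are clamped to
``1/(2n)`` away from the boundary to avoid degenerate log terms.  A
phenotype-frequency mode computes H and I directly on band frequencies
for comparison, since published dominant-marker studies are often silent
about which scale they used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .band_data import BandMatrix, band_frequencies

__all__ = [
    "DiversitySummary",
    "count_bands",
    "estimate_allele_freq_dominant",
    "nei_gene_diversity",
    "shannon_index",
    "diversity_table",
    "aggregate_primer_counts",
]


@dataclass
class DiversitySummary:
    """TNB/NPB/PPB plus mean H and I for one scope (primer/type/overall)."""

    scope: str
    tnb: int
    npb: int
    ppb: float
    H: float = float("nan")
    I: float = float("nan")


# -- band counting ---------------------------------------------------------

def _polymorphic_mask(m: BandMatrix) -> np.ndarray:
    """A locus is polymorphic iff both 0 and 1 are observed (missing-aware)."""
    v = m.values
    has0 = np.nansum(v == 0.0, axis=0) > 0
    has1 = np.nansum(v == 1.0, axis=0) > 0
    return has0 & has1


def count_bands(m: BandMatrix, group_by: str = "all") -> list[DiversitySummary]:
    """TNB/NPB/PPB per scope.

    ``group_by`` is one of ``"all"``, ``"type"`` (marker type) or
    ``"primer"``.  Counts are invariant under sample and band reordering.
    """
    if m.n_loci == 0:
        raise ValueError("empty band matrix")
    poly = _polymorphic_mask(m)
    if group_by == "all":
        scopes = {"all": np.ones(m.n_loci, dtype=bool)}
    elif group_by == "type":
        keys = pd.unique(pd.Series(m.primer_types))
        scopes = {k: np.array([t == k for t in m.primer_types]) for k in keys}
    elif group_by == "primer":
        keys = pd.unique(pd.Series(m.primer_ids))
        scopes = {k: np.array([p == k for p in m.primer_ids]) for k in keys}
    else:
        raise ValueError(f"group_by must be all/type/primer, got {group_by!r}")
    out = []
    for name, mask in scopes.items():
        tnb = int(mask.sum())
        if tnb == 0:
            raise ValueError(f"scope {name!r} contains no bands")
        npb = int(poly[mask].sum())
        out.append(DiversitySummary(name, tnb, npb, 100.0 * npb / tnb))
    return out


# -- allele-frequency estimation ------------------------------------------

def estimate_allele_freq_dominant(
    band_freq, n: int, method: str = "sqrt"
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate (p, q) = (presence, null) allele frequencies from band frequency.

    ``sqrt``: q = sqrt(1 - band_freq) under HWE.  ``lynch_milligan``
    applies the Lynch & Milligan (1994) bias correction

        q = sqrt(x) / (1 - var(x) / (8 x^2)),  x = 1 - band_freq,

    with ``var(x) = x (1 - x) / n`` the binomial sampling variance of the
    null-homozygote phenotype frequency.  Boundary frequencies (0 or 1)
    are clamped to 1/(2n) from the edge before estimation.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    f = np.atleast_1d(np.asarray(band_freq, dtype=float))
    if np.any((f < 0) | (f > 1)):
        raise ValueError("band frequency outside [0, 1]")
    x = 1.0 - f                       # null-homozygote phenotype frequency
    if method == "sqrt":
        q = np.sqrt(x)
    elif method == "lynch_milligan":
        xs = np.maximum(x, 1e-12)     # guard the boundary before correcting
        var_x = xs * (1.0 - xs) / n
        q = np.sqrt(xs) / (1.0 - var_x / (8.0 * xs**2))
    else:
        raise ValueError(f"unknown method {method!r}")
    # finite-sample clamp: monomorphic loci sit 1/(2n) from the boundary
    eps = 1.0 / (2.0 * n)
    q = np.clip(q, eps, 1.0 - eps)
    return 1.0 - q, q


def _allele_freqs(m: BandMatrix, method: str, scale: str):
    f = band_frequencies(m)
    if scale == "phenotype":
        eps = 1.0 / (2.0 * m.n_samples)
        p = np.clip(f, eps, 1.0 - eps)
        return p, 1.0 - p
    return estimate_allele_freq_dominant(f, m.n_samples, method=method)


def nei_gene_diversity(
    m: BandMatrix, method: str = "sqrt", scale: str = "allele"
) -> tuple[np.ndarray, float]:
    """Nei's gene diversity H = 2pq per locus, and its unweighted mean.

    ``scale="allele"`` (default) uses HWE-estimated allele frequencies;
    ``scale="phenotype"`` treats band frequencies as the diversity scale.
    """
    p, q = _allele_freqs(m, method, scale)
    h = 2.0 * p * q
    return h, float(h.mean())


def shannon_index(
    m: BandMatrix, method: str = "sqrt", scale: str = "allele"
) -> tuple[np.ndarray, float]:
    """Shannon's information index I = -p ln p - q ln q per locus, and mean."""
    p, q = _allele_freqs(m, method, scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        i = -np.where(p > 0, p * np.log(p), 0.0) - np.where(q > 0, q * np.log(q), 0.0)
    return i, float(i.mean())


# -- table assembly --------------------------------------------------------

def diversity_table(
    m: BandMatrix, group_by: str = "type", method: str = "sqrt", scale: str = "allele"
) -> pd.DataFrame:
    """Per-scope diversity table (TNB, NPB, PPB, H, I) as a DataFrame."""
    counts = count_bands(m, group_by=group_by)
    rows = []
    for summ in counts:
        if group_by == "all":
            sub = m
        elif group_by == "type":
            sub = m.select_loci(np.array([t == summ.scope for t in m.primer_types]))
        else:
            sub = m.select_loci(np.array([p == summ.scope for p in m.primer_ids]))
        _, H = nei_gene_diversity(sub, method=method, scale=scale)
        _, I = shannon_index(sub, method=method, scale=scale)
        rows.append(
            {"scope": summ.scope, "TNB": summ.tnb, "NPB": summ.npb,
             "PPB": summ.ppb, "H": H, "I": I}
        )
    return pd.DataFrame(rows)


def aggregate_primer_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-primer TNB/NPB table to marker-type and overall rows.

    Input columns: primer_id, primer_type, tnb, npb.  Output rows carry
    n_primers, TNB, NPB, PPB, mean bands/primer and mean polymorphic
    bands/primer (EMR) per marker type plus an 'all' row.  This is the
    aggregation-only path that needs no band matrix, only published
    per-primer counts.
    """
    need = {"primer_id", "primer_type", "tnb", "npb"}
    if not need <= set(counts.columns):
        raise ValueError(f"per-primer table must have columns {sorted(need)}")
    if (counts["npb"] > counts["tnb"]).any():
        bad = counts.loc[counts["npb"] > counts["tnb"], "primer_id"].iloc[0]
        raise ValueError(f"NPB > TNB for primer {bad!r}")
    rows = []
    groups = list(counts.groupby("primer_type", sort=False)) + [("all", counts)]
    for name, g in groups:
        tnb, npb, k = int(g["tnb"].sum()), int(g["npb"].sum()), len(g)
        rows.append(
            {"scope": name, "n_primers": k, "TNB": tnb, "NPB": npb,
             "PPB": 100.0 * npb / tnb,
             "mean_bands_per_primer": tnb / k,
             "EMR": npb / k}
        )
    return pd.DataFrame(rows)
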