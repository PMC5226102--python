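"""Marker-system efficiency scores: Ib, Ib_av, EMR and MI.

Band informativeness Ib = 1 - 2|0.5 - p| peaks at band frequency 0.5
(a band present in half the samples discriminates best) and vanishes at
monomorphic loci.  Ib_av averages Ib over a marker system's bands.  The
effective multiplex ratio EMR is the mean number of polymorphic bands per
primer, and the marker index MI = EMR * Ib_av combines per-assay yield
with per-band information content — the standard single-number comparison
of dominant marker systems.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .band_data import BandMatrix, band_frequencies
from .diversity import _polymorphic_mask, aggregate_primer_counts

__all__ = [
    "MarkerEfficiencySummary",
    "band_informativeness",
    "ib_av",
    "effective_multiplex_ratio",
    "marker_index",
    "efficiency_table",
    "efficiency_from_primer_counts",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (table convention: 4.655 -> 4.66)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MarkerEfficiencySummary:
    """Efficiency scores for one marker type."""

    scope: str
    n_primers: int
    ib_av: float
    emr: float
    mi: float


def band_informativeness(pi) -> np.ndarray | float:
    """Ib = 1 - 2|0.5 - pi| for band frequency pi (vectorised)."""
    p = np.asarray(pi, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("band frequency outside [0, 1]")
    out = 1.0 - 2.0 * np.abs(0.5 - p)
    return float(out) if out.ndim == 0 else out


def ib_av(m: BandMatrix, scope: str | None = None, ib_scope: str = "all") -> float:
    """Mean band informativeness over a marker type's bands.

    ``scope`` restricts to one primer type (None = whole matrix).
    ``ib_scope="all"`` averages over every scored band (monomorphic bands
    contribute Ib = 0); ``"polymorphic"`` averages over polymorphic bands
    only.
    """
    mask = np.ones(m.n_loci, dtype=bool)
    if scope is not None:
        mask &= np.array([t == scope for t in m.primer_types])
    if ib_scope == "polymorphic":
        mask &= _polymorphic_mask(m)
    elif ib_scope != "all":
        raise ValueError(f"ib_scope must be all/polymorphic, got {ib_scope!r}")
    if not mask.any():
        raise ValueError(f"no bands in scope {scope!r}")
    freqs = band_frequencies(m)[mask]
    return float(np.mean(band_informativeness(freqs)))


def effective_multiplex_ratio(per_primer_npb) -> float:
    """EMR = mean polymorphic bands per primer (sum NPB / number of primers)."""
    npb = np.asarray(per_primer_npb, dtype=float)
    if npb.size == 0:
        raise ValueError("no primers in scope")
    return float(npb.sum() / npb.size)


def marker_index(emr: float, ib_av_value: float) -> float:
    """MI = EMR * Ib_av (full precision; round for table display only)."""
    if emr < 0 or ib_av_value < 0:
        raise ValueError("EMR and Ib_av must be non-negative")
    return emr * ib_av_value


def efficiency_table(m: BandMatrix, ib_scope: str = "all") -> pd.DataFrame:
    """Per-marker-type efficiency table computed from a band matrix.

    Columns: n_primers, TNB, NPB, PPB, mean bands/primer, Ib_av, EMR, MI.
    """
    poly = _polymorphic_mask(m)
    rows = []
    for ptype in pd.unique(pd.Series(m.primer_types)):
        mask = np.array([t == ptype for t in m.primer_types])
        primers = pd.unique(pd.Series([p for p, t in zip(m.primer_ids, m.primer_types) if t == ptype]))
        npb_per_primer = [
            int(np.sum(poly & np.array([p == prim for p in m.primer_ids])))
            for prim in primers
        ]
        emr = effective_multiplex_ratio(npb_per_primer)
        iv = ib_av(m, scope=ptype, ib_scope=ib_scope)
        tnb, npb = int(mask.sum()), int(poly[mask].sum())
        rows.append(
            {"scope": ptype, "n_primers": len(primers), "TNB": tnb, "NPB": npb,
             "PPB": 100.0 * npb / tnb, "mean_bands_per_primer": tnb / len(primers),
             "Ib_av": iv, "EMR": emr, "MI": marker_index(emr, iv)}
        )
    return pd.DataFrame(rows)


def efficiency_from_primer_counts(
    counts: pd.DataFrame, ib_av_by_type: dict[str, float]
) -> pd.DataFrame:
    """EMR and MI from a published per-primer TNB/NPB table plus Ib_av values.

    The aggregation-only path: EMR comes from the NPB column; MI = EMR *
    the supplied per-type Ib_av.  Adds rounded 2-decimal display columns.
    """
    agg = aggregate_primer_counts(counts)
    agg = agg[agg["scope"] != "all"].copy()
    agg["Ib_av"] = agg["scope"].map(ib_av_by_type)
    if agg["Ib_av"].isna().any():
        missing = agg.loc[agg["Ib_av"].isna(), "scope"].tolist()
        raise ValueError(f"no Ib_av supplied for marker types: {missing}")
    agg["MI"] = agg["EMR"] * agg["Ib_av"]
    agg["EMR_2dp"] = agg["EMR"].map(lambda x: round_half_up(x, 2))
    agg["MI_2dp"] = agg["MI"].map(lambda x: round_half_up(x, 2))
    return agg.reset_index(drop=True)
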