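"""Data model and I/O for dominant-marker band presence/absence matrices.

Dominant marker systems (ISSR, SCoT, EST-SSR, RAPD, AFLP ...) score each
amplified band as present (1) or absent (0) in each sample; heterozygotes
are indistinguishable from dominant homozygotes.  The universal container
here is :class:`BandMatrix`: samples in rows, band loci in columns, with
each locus annotated by the primer that amplified it and the primer's
marker type.  Missing scores (failed lanes) are carried as NaN and every
downstream computation is pairwise/column-complete.

File format
-----------
A band matrix TSV has two comment header lines giving per-column primer
annotation, then a band-id header row, then one row per sample::

    #primer_id<TAB><TAB>P1<TAB>P1<TAB>P2
    #primer_type<TAB><TAB>ISSR<TAB>ISSR<TAB>SCoT
    sample_id<TAB>b1<TAB>b2<TAB>b3
    s1<TAB>1<TAB>0<TAB>NA

Sample metadata is a plain TSV with columns
``sample_id, plant_id, name, ecotype, origin``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: recognised marker-type labels; user-defined labels are also accepted
STANDARD_PRIMER_TYPES = ("ISSR", "SCoT", "EST-SSR")

MISSING = np.nan


class BandDataError(ValueError):
    """Raised on malformed band matrices or metadata."""


@dataclass(frozen=True)
class BandLocus:
    """One scored band: an anonymous dominant locus.

    ``band_frequency`` is the fraction of non-missing samples showing the
    band (the presence-phenotype frequency), filled in by
    :meth:`BandMatrix.loci`.
    """

    band_id: str
    primer_id: str
    primer_type: str
    band_frequency: float = float("nan")


@dataclass
class BandMatrix:
    """Samples x band-loci binary matrix with primer annotation.

    Parameters
    ----------
    samples
        Ordered unique sample IDs (rows).
    band_ids, primer_ids, primer_types
        Ordered per-column annotation, equal length.
    values
        float array of shape (n_samples, n_loci) with entries 0.0, 1.0 or
        NaN for missing.
    """

    samples: list[str]
    band_ids: list[str]
    primer_ids: list[str]
    primer_types: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, L = self.values.shape
        if len(self.samples) != n:
            raise BandDataError(
                f"{len(self.samples)} sample IDs for {n} matrix rows"
            )
        if not (len(self.band_ids) == len(self.primer_ids) == len(self.primer_types) == L):
            raise BandDataError("per-locus annotation length mismatch")
        if len(set(self.samples)) != n:
            raise BandDataError("duplicate sample IDs")
        if len(set(self.band_ids)) != L:
            raise BandDataError("duplicate band IDs")
        ok = np.isnan(self.values) | (self.values == 0.0) | (self.values == 1.0)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise BandDataError(
                f"non-binary value {self.values[i, j]!r} at "
                f"(sample {self.samples[i]!r}, band {self.band_ids[j]!r})"
            )

    # -- basic properties -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def loci(self) -> list[BandLocus]:
        """Per-locus records with computed band frequencies."""
        freqs = band_frequencies(self)
        return [
            BandLocus(b, p, t, float(f))
            for b, p, t, f in zip(self.band_ids, self.primer_ids, self.primer_types, freqs)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Values as a DataFrame indexed by sample with band-id columns."""
        return pd.DataFrame(self.values, index=self.samples, columns=self.band_ids)

    def select_loci(self, keep: np.ndarray) -> "BandMatrix":
        """New matrix restricted to loci where boolean/index ``keep`` selects."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return BandMatrix(
            samples=list(self.samples),
            band_ids=[self.band_ids[i] for i in idx],
            primer_ids=[self.primer_ids[i] for i in idx],
            primer_types=[self.primer_types[i] for i in idx],
            values=self.values[:, idx],
        )

    def select_samples(self, ids: list[str]) -> "BandMatrix":
        """New matrix restricted to the given sample IDs (in given order)."""
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise BandDataError(f"unknown sample IDs: {missing[:5]}")
        idx = [pos[s] for s in ids]
        return BandMatrix(
            samples=list(ids),
            band_ids=list(self.band_ids),
            primer_ids=list(self.primer_ids),
            primer_types=list(self.primer_types),
            values=self.values[idx, :],
        )


# -- sample metadata -------------------------------------------------------

META_COLUMNS = ["sample_id", "plant_id", "name", "ecotype", "origin"]


def read_sample_meta(path) -> pd.DataFrame:
    """Read a sample-metadata TSV (sample_id, plant_id, name, ecotype, origin)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise BandDataError(f"metadata file missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise BandDataError(f"duplicate sample_id in metadata: {dup!r}")
    return meta


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# -- band matrix I/O -------------------------------------------------------

def read_band_matrix(path) -> BandMatrix:
    """Read a band matrix TSV (see module docstring for the layout).

    Raises
    ------
    BandDataError
        On a non-binary cell (naming the sample and band), duplicate IDs,
        or missing header lines.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3 or not lines[0].startswith("#primer_id") or not lines[1].startswith("#primer_type"):
        raise BandDataError(
            f"{path}: expected '#primer_id' and '#primer_type' header lines"
        )
    primer_ids = lines[0].split("\t")[1:]
    primer_types = lines[1].split("\t")[1:]
    header = lines[2].split("\t")
    band_ids = header[1:]
    samples: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[3:]:
        if not ln:
            continue
        cells = ln.split("\t")
        samples.append(cells[0])
        row = []
        for band, cell in zip(band_ids, cells[1:]):
            if cell in ("0", "1"):
                row.append(float(cell))
            elif cell in ("NA", "", "nan", "NaN"):
                row.append(MISSING)
            else:
                raise BandDataError(
                    f"non-binary cell {cell!r} at (sample {cells[0]!r}, band {band!r})"
                )
        if len(row) != len(band_ids):
            raise BandDataError(
                f"sample {cells[0]!r}: {len(row)} cells for {len(band_ids)} bands"
            )
        rows.append(row)
    m = BandMatrix(samples, band_ids, primer_ids, primer_types, np.array(rows, dtype=float))
    logger.info("read band matrix %s: %d samples x %d loci", path, m.n_samples, m.n_loci)
    return m


def write_band_matrix(m: BandMatrix, path) -> None:
    """Write the TSV layout read by :func:`read_band_matrix`."""
    with open(path, "w") as fh:
        fh.write("#primer_id\t" + "\t".join(m.primer_ids) + "\n")
        fh.write("#primer_type\t" + "\t".join(m.primer_types) + "\n")
        fh.write("sample_id\t" + "\t".join(m.band_ids) + "\n")
        for i, s in enumerate(m.samples):
            cells = [
                "NA" if np.isnan(v) else str(int(v)) for v in m.values[i]
            ]
            fh.write(s + "\t" + "\t".join(cells) + "\n")


# -- frequencies and filtering ---------------------------------------------

def band_frequencies(m: BandMatrix) -> np.ndarray:
    """Per-locus presence frequency over non-missing samples.

    Raises
    ------
    BandDataError
        If any locus is missing in every sample (listing the band IDs).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        counts = np.sum(~np.isnan(m.values), axis=0)
        if (counts == 0).any():
            bad = [m.band_ids[i] for i in np.flatnonzero(counts == 0)]
            raise BandDataError(f"all-missing band columns: {bad}")
        freq = np.nanmean(m.values, axis=0)
    return freq


def maf_filter(
    m: BandMatrix,
    threshold: float = 0.05,
    two_sided: bool = False,
) -> tuple[BandMatrix, list[str]]:
    """Remove rare bands before LD / structure analysis.

    Drops loci with band frequency strictly below ``threshold`` (rare
    presence).  With ``two_sided=True`` loci with frequency strictly above
    ``1 - threshold`` (near-fixed presence) are dropped as well; the default
    is one-sided, removing only low-frequency bands.

    Returns the filtered matrix and the list of removed band IDs.
    """
    if not 0.0 <= threshold <= 0.5:
        raise BandDataError(f"threshold must be in [0, 0.5], got {threshold}")
    freq = band_frequencies(m)
    drop = freq < threshold
    if two_sided:
        drop |= freq > 1.0 - threshold
    removed = [m.band_ids[i] for i in np.flatnonzero(drop)]
    if drop.all():
        raise BandDataError(
            "MAF filter removed every band; lower the threshold"
        )
    if removed:
        logger.info("MAF filter (<%g%s) removed %d of %d bands",
                    threshold, ", two-sided" if two_sided else "", len(removed), m.n_loci)
    return m.select_loci(~drop), removed


def split_by_group(
    m: BandMatrix, meta: pd.DataFrame, key: str = "ecotype"
) -> dict[str, BandMatrix]:
    """Partition samples by a metadata column (e.g. ecotype or subpopulation).

    Every sample in ``m`` must have a metadata row; group levels with zero
    samples in the matrix are omitted with a warning.
    """
    if key not in meta.columns:
        raise BandDataError(f"metadata has no column {key!r}")
    lookup = meta.set_index("sample_id")[key]
    absent = [s for s in m.samples if s not in lookup.index]
    if absent:
        raise BandDataError(f"samples without metadata: {absent[:5]}")
    out: dict[str, BandMatrix] = {}
    labels = lookup.loc[m.samples]
    for level in pd.unique(labels):
        ids = [s for s, g in zip(m.samples, labels) if g == level]
        out[str(level)] = m.select_samples(ids)
    declared = set(pd.unique(lookup)) - set(out)
    if declared:
        logger.warning("group levels with no samples in matrix omitted: %s", sorted(declared))
    return out


def group_labels(m: BandMatrix, meta: pd.DataFrame, key: str = "ecotype") -> np.ndarray:
    """Metadata group label per matrix sample, in matrix order."""
    if key not in meta.columns:
        raise BandDataError(f"metadata has no column {key!r}")
    lookup = meta.set_index("sample_id")[key]
    absent = [s for s in m.samples if s not in lookup.index]
    if absent:
        raise BandDataError(f"samples without metadata: {absent[:5]}")
    return lookup.loc[m.samples].to_numpy()
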