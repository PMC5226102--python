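"""Synthetic dominant-marker datasets with controlled population structure.

Generates diploid band presence/absence data under the Balding-Nichols
model: each locus has an ancestral dominant-allele frequency
``p_anc ~ Beta(a, b)``; each latent subpopulation draws its own frequency

    p_k ~ Beta(p_anc * (1 - F) / F,  (1 - p_anc) * (1 - F) / F)

so that ``F`` (``fst``) is the expected Wright differentiation among
subpopulations.  Each sample carries admixture proportions ``q_i`` over the
K subpopulations; at every locus two allele copies are drawn, each from a
subpopulation chosen by ``q_i`` and carrying the presence allele with that
subpopulation's frequency.  The scored band is present iff at least one
copy carries the presence allele — the HWE dominance collapse, so a locus
with allele frequency p shows the band at frequency ``1 - (1-p)^2``.

Linkage disequilibrium is injected mechanically: loci are grouped into
blocks and, with probability ``ld_copy_prob``, a locus's diploid genotype
column is replaced by a copy of its block anchor (optionally only within
chosen subpopulations, producing subpopulation-specific LD contrasts).

The default configuration mirrors a 134-accession switchgrass collection:
two latent subpopulations (91 + 43 samples), 7 lowland / 127 upland
ecotype labels, 51 primers (16 ISSR / 20 SCoT / 15 EST-SSR) with mean
band counts 13.75 / 22.25 / 8.53 per primer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .band_data import META_COLUMNS, BandMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "expected_band_frequency",
    "paper_scale_config",
]

#: primer counts per marker type of the emulated study design
DEFAULT_PRIMERS = {"ISSR": 16, "SCoT": 20, "EST-SSR": 15}
#: mean scored bands per primer per marker type of the emulated design
DEFAULT_BANDS_PER_PRIMER = {"ISSR": 13.75, "SCoT": 22.25, "EST-SSR": 8.53}


@dataclass
class SimConfig:
    """Generator settings.

    Parameters
    ----------
    n_samples
        Total diploid samples.
    group_sizes
        Samples per latent subpopulation; must sum to ``n_samples``.
    n_primers, bands_per_primer
        Primer count and mean band count per marker type; the per-primer
        band count is drawn as ``1 + Poisson(mean - 1)``.
    fst
        Balding-Nichols differentiation among subpopulations, in (0, 1).
    admixture_alpha
        Symmetric Dirichlet concentration of the admixture noise added to
        each sample's own-subpopulation membership; 0 means no admixture
        (every sample is 100 % its subpopulation of origin).
    admixture_own_weight
        Extra Dirichlet weight on the sample's own subpopulation; larger
        values concentrate membership near 1.
    ld_block_size, ld_copy_prob
        LD injection: loci are tiled into blocks of this size and each
        non-anchor locus copies its anchor's genotypes with this
        probability.  ``ld_groups`` restricts the copying to samples whose
        subpopulation of origin is in the given set (None = all samples),
        producing elevated within-group LD.
    ancestral_beta
        (a, b) of the ancestral dominant-allele frequency Beta prior.
    n_lowland
        Leading samples of subpopulation 1 labelled LL in the metadata;
        the rest are UL.
    """

    n_samples: int = 134
    group_sizes: tuple[int, ...] = (91, 43)
    n_primers: dict = field(default_factory=lambda: dict(DEFAULT_PRIMERS))
    bands_per_primer: dict = field(default_factory=lambda: dict(DEFAULT_BANDS_PER_PRIMER))
    fst: float = 0.35
    admixture_alpha: float = 0.15
    admixture_own_weight: float = 2.0
    ld_block_size: int = 1
    ld_copy_prob: float = 0.0
    ld_groups: tuple[int, ...] | None = None
    ancestral_beta: tuple[float, float] = (0.6, 0.6)
    n_lowland: int = 7
    seed: int = 0

    def validate(self) -> None:
        if sum(self.group_sizes) != self.n_samples:
            raise ValueError(
                f"group_sizes {self.group_sizes} do not sum to n_samples {self.n_samples}"
            )
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must be in (0, 1), got {self.fst}")
        if any(g <= 0 for g in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0.0 <= self.ld_copy_prob <= 1.0:
            raise ValueError("ld_copy_prob must be in [0, 1]")
        if any(v <= 0 for v in self.n_primers.values()):
            raise ValueError("primer counts must be positive")


@dataclass
class SimTruth:
    """Ground truth kept alongside a simulated dataset.

    ``genotypes`` holds the pre-collapse diploid presence-allele counts
    (0/1/2 per sample x locus); ``band = genotypes >= 1``.
    """

    ancestral_freq: np.ndarray          # (L,) ancestral allele frequency
    subpop_freq: np.ndarray             # (K, L) per-subpopulation allele frequency
    admixture: np.ndarray               # (n, K) true membership proportions
    origin: np.ndarray                  # (n,) subpopulation of origin
    genotypes: np.ndarray               # (n, L) diploid allele counts


def expected_band_frequency(p) -> np.ndarray | float:
    """Band (presence phenotype) frequency for dominant-allele frequency p.

    Under HWE a band is absent only in the recessive homozygote, so the
    expected phenotype frequency is ``1 - (1 - p)**2``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    out = 1.0 - (1.0 - p) ** 2
    return float(out) if out.ndim == 0 else out


def _draw_locus_layout(cfg: SimConfig, rng: np.random.Generator):
    """Per-locus band/primer/type labels; counts 1 + Poisson(mean-1)."""
    band_ids, primer_ids, primer_types = [], [], []
    for ptype, n_prim in cfg.n_primers.items():
        mean = float(cfg.bands_per_primer[ptype])
        counts = 1 + rng.poisson(max(mean - 1.0, 0.0), size=n_prim)
        for j, c in enumerate(counts, start=1):
            pid = f"{ptype}-P{j:02d}"
            for b in range(1, int(c) + 1):
                band_ids.append(f"{pid}_b{b:02d}")
                primer_ids.append(pid)
                primer_types.append(ptype)
    return band_ids, primer_ids, primer_types


def simulate_dataset(cfg: SimConfig, seed: int | None = None):
    """Simulate a band matrix with metadata and ground truth.

    Returns
    -------
    (BandMatrix, DataFrame, SimTruth)
        The 0/1 band matrix, a sample-metadata table (ecotype UL/LL and
        latent subpopulation of origin), and the generating truth.

    Deterministic for a fixed config and seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    K = len(cfg.group_sizes)
    n = cfg.n_samples

    band_ids, primer_ids, primer_types = _draw_locus_layout(cfg, rng)
    L = len(band_ids)

    a, b = cfg.ancestral_beta
    p_anc = rng.beta(a, b, size=L)
    # keep ancestral frequencies off the boundary so BN shapes stay valid
    p_anc = np.clip(p_anc, 0.01, 0.99)
    F = cfg.fst
    shape1 = p_anc * (1.0 - F) / F
    shape2 = (1.0 - p_anc) * (1.0 - F) / F
    subpop_freq = rng.beta(shape1, shape2, size=(K, L))

    origin = np.repeat(np.arange(K), cfg.group_sizes)
    if cfg.admixture_alpha <= 0.0:
        q = np.zeros((n, K))
        q[np.arange(n), origin] = 1.0
    else:
        conc = np.full((n, K), cfg.admixture_alpha)
        conc[np.arange(n), origin] += cfg.admixture_own_weight
        q = np.vstack([rng.dirichlet(conc[i]) for i in range(n)])

    # two allele copies per sample x locus, each from a q-chosen subpopulation
    geno = np.zeros((n, L), dtype=np.int8)
    for _copy in range(2):
        z = np.vstack([rng.choice(K, size=L, p=q[i]) for i in range(n)])
        geno += (rng.random((n, L)) < subpop_freq[z, np.arange(L)]).astype(np.int8)

    # LD injection: tile loci into blocks, copy anchor genotype columns
    if cfg.ld_block_size > 1 and cfg.ld_copy_prob > 0.0:
        if cfg.ld_groups is None:
            row_mask = np.ones(n, dtype=bool)
        else:
            row_mask = np.isin(origin, np.asarray(cfg.ld_groups))
        for start in range(0, L, cfg.ld_block_size):
            stop = min(start + cfg.ld_block_size, L)
            for j in range(start + 1, stop):
                if rng.random() < cfg.ld_copy_prob:
                    geno[row_mask, j] = geno[row_mask, start]

    bands = (geno >= 1).astype(float)
    samples = [f"S{i + 1:03d}" for i in range(n)]
    matrix = BandMatrix(samples, band_ids, primer_ids, primer_types, bands)

    ecotype = np.where(np.arange(n) < cfg.n_lowland, "LL", "UL")
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "plant_id": [f"PI9{i:05d}" for i in range(n)],
            "name": [f"ACC-{i + 1:03d}" for i in range(n)],
            "ecotype": ecotype,
            "origin": [f"subpop{g + 1}" for g in origin],
        },
        columns=META_COLUMNS,
    )
    truth = SimTruth(p_anc, subpop_freq, q, origin, geno)
    return matrix, meta, truth


def paper_scale_config(**overrides) -> SimConfig:
    """The default study-shaped configuration (134 samples, 51 primers).

    ``fst=0.35`` places among-ecotype AMOVA variance in the ~30 % regime
    observed for upland/lowland switchgrass collections.  Keyword
    overrides replace individual fields.
    """
    cfg = SimConfig()
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown SimConfig field {k!r}")
        setattr(cfg, k, v)
    return cfg
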