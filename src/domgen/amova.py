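"""Analysis of molecular variance (AMOVA) on squared distances.

Partitions band-profile variation among and within groups following
Excoffier's sums-of-squares construction: with N samples in G groups,

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_among  = SS_total - SS_within

with df_among = G - 1 and df_within = N - G.  The within component is
sigma2_b = MS_within and the among component

    sigma2_a = (MS_among - MS_within) / n0,
    n0 = (N - sum_g n_g^2 / N) / (G - 1),

the familiar average group size correction.  Phi_ST =
sigma2_a / (sigma2_a + sigma2_b) is the among-group fixation analogue;
negative among components are clamped to zero and flagged.  Significance
comes from permuting group labels across samples.

The distances supplied should be on a squared-Euclidean-compatible scale;
for 0/1 band profiles the Euclidean distance (squared = Hamming count) is
the conventional choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = ["AmovaResult", "amova_partition", "amova_permutation_test", "amova"]


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    clamped: bool = False
    p_value: float | None = None

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within


def _group_indices(groups) -> list[np.ndarray]:
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups.tolist()))  # order-preserving
    return [np.flatnonzero(groups == g) for g in levels]


def _phi_components(D2: np.ndarray, idx_groups: list[np.ndarray]):
    """SS and variance components from a squared-distance matrix."""
    N = D2.shape[0]
    G = len(idx_groups)
    iu = np.triu_indices(N, k=1)
    ss_total = D2[iu].sum() / N
    ss_within = 0.0
    for idx in idx_groups:
        if idx.size == 0:
            raise ValueError("empty group in AMOVA")
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_among = ss_total - ss_within
    df_among, df_within = G - 1, N - G
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    ms_among = ss_among / df_among
    sizes = np.array([idx.size for idx in idx_groups], dtype=float)
    n0 = (N - (sizes**2).sum() / N) / df_among
    sigma2_b = ms_within
    sigma2_a = (ms_among - ms_within) / n0
    return ss_among, ss_within, sigma2_a, sigma2_b, df_among, df_within


def amova_partition(d: DistanceMatrix, groups) -> AmovaResult:
    """Two-level AMOVA of a distance matrix given per-sample group labels.

    ``groups`` is a length-N sequence aligned with ``d.labels``.  Returns
    sums of squares, variance components, percentages and Phi_ST.  If all
    distances are zero the percentages are defined as (0, 100) with a
    warning; a negative among-group component is clamped to zero and
    flagged.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != d.n:
        raise ValueError(f"{groups.shape[0]} group labels for {d.n} samples")
    idx_groups = _group_indices(groups)
    if len(idx_groups) < 2:
        raise ValueError("AMOVA needs at least two groups")
    if not np.isfinite(d.values).all():
        raise ValueError("non-finite distances")
    D2 = d.values**2
    ss_a, ss_w, s2a, s2b, dfa, dfw = _phi_components(D2, idx_groups)

    clamped = False
    if s2a < 0:
        s2a, clamped = 0.0, True
        logger.info("negative among-group variance component clamped to 0")
    total = s2a + s2b
    if total <= 0:
        logger.warning("zero total variance; percentages defined as (0, 100)")
        pct_a, pct_w, phi = 0.0, 100.0, 0.0
    else:
        pct_a = 100.0 * s2a / total
        pct_w = 100.0 * s2b / total
        phi = s2a / total
    return AmovaResult(dfa, dfw, ss_a, ss_w, s2a, s2b, pct_a, pct_w, phi, clamped)


def amova_permutation_test(
    d: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> float:
    """Permutation p-value for Phi_ST by shuffling group labels.

    p = (1 + #{Phi_perm >= Phi_obs}) / (1 + n_perm); deterministic under
    ``seed``.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    groups = np.asarray(groups)
    obs = amova_partition(d, groups).phi_st
    rng = np.random.default_rng(seed)
    D2 = d.values**2
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        idx_groups = _group_indices(perm)
        _, _, s2a, s2b, _, _ = _phi_components(D2, idx_groups)
        s2a = max(s2a, 0.0)
        phi = s2a / (s2a + s2b) if (s2a + s2b) > 0 else 0.0
        if phi >= obs - 1e-12:
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


def amova(
    d: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> AmovaResult:
    """AMOVA partition plus permutation p-value in one call."""
    res = amova_partition(d, groups)
    res.p_value = amova_permutation_test(d, groups, n_perm=n_perm, seed=seed)
    return res
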