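"""Pairwise linkage disequilibrium r² between dominant band loci.

For two binary band columns A, B with presence frequencies pA, pB and
joint presence frequency pAB over the pairwise-complete samples,

    r² = (pAB - pA·pB)² / (pA (1-pA) pB (1-pB)),

the squared Pearson correlation of the two 0/1 columns.  Significance is
assessed with the allelic chi-square X² = n·r² on 1 df (a permutation
alternative is provided); no multiple-testing correction is applied to
the headline counts, matching the convention of reporting raw P < 0.001
pair fractions, but a Bonferroni threshold column is emitted for
information.  Inputs should be MAF-filtered (rare bands removed) so that
every column is polymorphic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .band_data import BandMatrix

__all__ = ["LDResult", "pairwise_r2", "r2_significance", "ld_summary", "stratified_ld"]


@dataclass
class LDResult:
    """All-pairs LD: condensed upper-triangle arrays plus locus labels."""

    band_ids: list[str]
    pair_i: np.ndarray = field(repr=False)   # first locus index per pair
    pair_j: np.ndarray = field(repr=False)
    r2: np.ndarray = field(repr=False)
    p_value: np.ndarray = field(repr=False)
    n_samples: np.ndarray = field(repr=False)  # pairwise-complete n per pair

    @property
    def n_pairs(self) -> int:
        return self.r2.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band_a": [self.band_ids[i] for i in self.pair_i],
                "band_b": [self.band_ids[j] for j in self.pair_j],
                "r2": self.r2,
                "p_value": self.p_value,
                "n": self.n_samples,
            }
        )


def _check_polymorphic(m: BandMatrix) -> None:
    v = m.values
    has0 = np.nansum(v == 0.0, axis=0) > 0
    has1 = np.nansum(v == 1.0, axis=0) > 0
    mono = ~(has0 & has1)
    if mono.any():
        bad = [m.band_ids[i] for i in np.flatnonzero(mono)][:5]
        raise ValueError(
            f"monomorphic bands reached the LD stage (MAF filter violated): {bad}"
        )


def pairwise_r2(m: BandMatrix, inter_primer_only: bool = False) -> LDResult:
    """r² and chi-square p-value for every unordered locus pair.

    ``inter_primer_only=True`` restricts to pairs of bands amplified by
    different primers.  Missing scores are handled pairwise-complete.
    """
    if m.n_loci < 2:
        raise ValueError("need at least two loci")
    _check_polymorphic(m)
    X = m.values
    n, L = X.shape
    obs = ~np.isnan(X)
    x1 = np.nan_to_num(X, nan=0.0)

    OB = obs.astype(float)
    n_pair = OB.T @ OB                      # pairwise-complete n
    s_ab = x1.T @ x1                        # joint presence counts
    s_a = x1.T @ OB                         # presence of A where B observed
    s_b = s_a.T
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = s_a / n_pair
        pb = s_b / n_pair
        pab = s_ab / n_pair
        var = pa * (1.0 - pa) * pb * (1.0 - pb)
        r2 = np.where(var > 0, (pab - pa * pb) ** 2 / np.where(var > 0, var, 1.0), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)

    iu, ju = np.triu_indices(L, k=1)
    if inter_primer_only:
        keep = np.array(
            [m.primer_ids[i] != m.primer_ids[j] for i, j in zip(iu, ju)]
        )
        iu, ju = iu[keep], ju[keep]
    r2_pairs = r2[iu, ju]
    n_pairs = n_pair[iu, ju]
    pvals = stats.chi2.sf(n_pairs * r2_pairs, df=1)
    return LDResult(list(m.band_ids), iu, ju, r2_pairs, pvals, n_pairs.astype(int))


def r2_significance(
    x,
    y,
    method: str = "chi2",
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """(r², p-value) for one pair of binary columns.

    ``chi2``: X² = n r² against chi-square(1).  ``permutation``: shuffle
    one column ``n_perm`` times, p = (1 + #{r²_perm >= r²_obs}) / (1 +
    n_perm), deterministic under ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 2:
        raise ValueError("need at least two complete observations")

    def _r2(a, b):
        va, vb = a.var(), b.var()
        if va <= 0 or vb <= 0:
            return 0.0
        c = np.mean(a * b) - a.mean() * b.mean()
        return float(np.clip(c * c / (va * vb), 0.0, 1.0))

    obs = _r2(x, y)
    if method == "chi2":
        return obs, float(stats.chi2.sf(n * obs, df=1))
    if method == "permutation":
        rng = np.random.default_rng(seed)
        count = sum(
            _r2(x, rng.permutation(y)) >= obs - 1e-15 for _ in range(n_perm)
        )
        return obs, (1.0 + count) / (1.0 + n_perm)
    raise ValueError(f"unknown method {method!r}")


def ld_summary(res: LDResult, alpha: float = 0.001, r2_cut: float = 0.1) -> dict:
    """Scope-level LD summary.

    Counts of pairs significant at ``alpha``, of pairs jointly passing
    r² > ``r2_cut`` and p < alpha, mean/min/max r² over all pairs and
    over significant pairs, plus the Bonferroni-adjusted alpha for
    information.
    """
    sig = res.p_value < alpha
    joint = sig & (res.r2 > r2_cut)
    total = res.n_pairs
    out = {
        "n_pairs": int(total),
        "n_significant": int(sig.sum()),
        "frac_significant": float(sig.sum() / total) if total else float("nan"),
        "n_r2_and_significant": int(joint.sum()),
        "frac_r2_and_significant": float(joint.sum() / total) if total else float("nan"),
        "mean_r2_all": float(res.r2.mean()) if total else float("nan"),
        "min_r2_all": float(res.r2.min()) if total else float("nan"),
        "max_r2_all": float(res.r2.max()) if total else float("nan"),
        "alpha": alpha,
        "r2_cut": r2_cut,
        "bonferroni_alpha": alpha / total if total else float("nan"),
    }
    if sig.any():
        out["mean_r2_significant"] = float(res.r2[sig].mean())
        out["min_r2_significant"] = float(res.r2[sig].min())
        out["max_r2_significant"] = float(res.r2[sig].max())
    else:
        out["mean_r2_significant"] = float("nan")
        out["min_r2_significant"] = float("nan")
        out["max_r2_significant"] = float("nan")
    return out


def stratified_ld(
    m: BandMatrix,
    strata: dict[str, list[str]],
    maf_threshold: float = 0.05,
    alpha: float = 0.001,
    r2_cut: float = 0.1,
) -> dict[str, dict]:
    """Per-stratum LD summaries (e.g. per inferred subpopulation).

    Band frequencies and the MAF filter are recomputed inside each
    stratum, matching how subpopulation LD is analysed after structure
    assignment.
    """
    from .band_data import maf_filter

    out = {}
    for name, ids in strata.items():
        sub = m.select_samples(list(ids))
        filtered, _ = maf_filter(sub, threshold=maf_threshold, two_sided=True)
        res = pairwise_r2(filtered)
        out[name] = ld_summary(res, alpha=alpha, r2_cut=r2_cut)
    return out
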