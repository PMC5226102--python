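"""Bayesian admixture clustering for dominant band data.

A simplified model-based clustering in the STRUCTURE tradition, adapted
to dominant 0/1 band phenotypes: each of K clusters has a band frequency
p_kl per locus, each sample has admixture proportions q_i over clusters,
and each observed band arises from a latent cluster of origin z_il,

    z_il | q  ~ Categorical(q_i),
    x_il | z  ~ Bernoulli(p_{z_il, l}).

This treats the band phenotype itself as the Bernoulli observation — a
deliberate simplification that skips the recessive-genotype integration
of STRUCTURE's dominant-data model, and uses independent (not
correlated) cluster frequencies.  The collapsed quantities of interest
(Q, P, model evidence, and the downstream Evanno ΔK / membership
assignment logic) follow the standard procedure.

Gibbs sweeps alternate

    z_il | q, p  ~ Categorical( q_ik * p_kl^x * (1-p_kl)^(1-x) ),
    p_kl | z     ~ Beta(a + #{x=1, z=k}, b + #{x=0, z=k}),
    q_i  | z     ~ Dirichlet(alpha + per-cluster counts),

and the model evidence is estimated as LnP(D) = mean(lnL) - var(lnL)/2
over the retained trace, the harmonic-style estimator STRUCTURE reports.
Missing band scores are simply excluded from counts and likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .band_data import BandMatrix

__all__ = [
    "StructureFit",
    "gibbs_admixture",
    "evanno_delta_k",
    "assign_membership",
    "align_runs",
    "structure_run_grid",
]


@dataclass
class StructureFit:
    """One admixture run: posterior means and evidence."""

    K: int
    samples: list[str]
    Q: np.ndarray = field(repr=False)        # (n, K) posterior mean admixture
    P: np.ndarray = field(repr=False)        # (K, L) posterior mean band freqs
    lnl_trace: np.ndarray = field(repr=False)
    ln_p_d: float = float("nan")
    seed: int = 0
    burn_in: int = 0
    n_iter: int = 0
    thin: int = 1


def gibbs_admixture(
    m: BandMatrix,
    K: int,
    burn_in: int = 2000,
    n_iter: int = 10000,
    thin: int = 10,
    seed: int = 0,
    alpha: float = 1.0,
    beta_prior: tuple[float, float] = (1.0, 1.0),
) -> StructureFit:
    """Fit the K-cluster admixture model by Gibbs sampling.

    ``n_iter`` sweeps are retained after ``burn_in`` discarded sweeps,
    recording every ``thin``-th state.  Deterministic under ``seed``.
    The input should normally be MAF-filtered (rare bands removed).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if m.n_loci < 1 or m.n_samples < 2:
        raise ValueError("need >= 2 samples and >= 1 locus")
    rng = np.random.default_rng(seed)
    X = m.values
    n, L = X.shape
    obs = ~np.isnan(X)
    x1 = np.nan_to_num(X, nan=0.0)            # presence indicator (0 at missing)
    x0 = obs.astype(float) - x1               # absence indicator
    a, b = beta_prior

    p = rng.uniform(0.2, 0.8, size=(K, L))
    q = rng.dirichlet(np.full(K, alpha), size=n)

    sum_q = np.zeros((n, K))
    sum_p = np.zeros((K, L))
    lnl_rec: list[float] = []
    n_rec = 0
    eps = 1e-12

    for sweep in range(burn_in + n_iter):
        # w[i,l,k] = q_ik * p_kl^x * (1-p_kl)^(1-x); missing -> prior q only
        like = np.where(X[:, :, None] == 1.0, p.T[None, :, :], (1.0 - p.T)[None, :, :])
        like = np.where(obs[:, :, None], like, 1.0)
        w = q[:, None, :] * like
        tot = w.sum(axis=2)
        lnl = float(np.log(np.maximum(tot, eps))[obs].sum())

        probs = w / np.maximum(tot, eps)[:, :, None]
        u = rng.random((n, L))
        z = (np.cumsum(probs, axis=2) < u[:, :, None]).sum(axis=2)
        z = np.minimum(z, K - 1)
        Z = np.eye(K, dtype=float)[z]          # (n, L, K) one-hot

        n1 = np.einsum("ilk,il->kl", Z, x1)
        n0 = np.einsum("ilk,il->kl", Z, x0)
        p = rng.beta(a + n1, b + n0)
        p = np.clip(p, 1e-9, 1.0 - 1e-9)

        counts = np.einsum("ilk,il->ik", Z, obs.astype(float))
        g = rng.gamma(alpha + counts)
        q = g / np.maximum(g.sum(axis=1, keepdims=True), eps)

        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            sum_q += q
            sum_p += p
            lnl_rec.append(lnl)
            n_rec += 1

    Q = sum_q / n_rec
    Q /= Q.sum(axis=1, keepdims=True)
    P = sum_p / n_rec
    trace = np.asarray(lnl_rec)
    ln_p_d = float(trace.mean() - trace.var() / 2.0)
    return StructureFit(
        K=K, samples=list(m.samples), Q=Q, P=P, lnl_trace=trace,
        ln_p_d=ln_p_d, seed=seed, burn_in=burn_in, n_iter=n_iter, thin=thin,
    )


def structure_run_grid(
    m: BandMatrix,
    k_range=range(1, 7),
    n_reps: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> dict[int, list[StructureFit]]:
    """Replicate runs over a K grid; per-run seeds derive from ``seed``."""
    runs: dict[int, list[StructureFit]] = {}
    for K in k_range:
        runs[K] = [
            gibbs_admixture(m, K, seed=seed + 1000 * K + r, **fit_kwargs)
            for r in range(n_reps)
        ]
    return runs


def evanno_delta_k(runs: dict[int, list[StructureFit]]) -> pd.DataFrame:
    """Evanno ΔK table from replicate runs over a contiguous K range.

    ΔK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)) using
    the sample sd over replicates; defined for interior K only.  The
    result carries columns K, mean_lnpd, sd_lnpd, delta_k and the argmax
    in ``df.attrs["best_k"]``.
    """
    ks = sorted(runs)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need a contiguous K range with at least 3 values")
    for K in ks:
        if len(runs[K]) < 2:
            raise ValueError(f"need >= 2 replicate runs per K (K={K})")
    means = {K: float(np.mean([f.ln_p_d for f in runs[K]])) for K in ks}
    sds = {K: float(np.std([f.ln_p_d for f in runs[K]], ddof=1)) for K in ks}
    rows = []
    for K in ks:
        dk = np.nan
        if ks[0] < K < ks[-1]:
            if sds[K] == 0.0:
                raise ValueError(
                    f"sd of LnP(D) is 0 at K={K}; run more replicates"
                )
            dk = abs(means[K + 1] - 2.0 * means[K] + means[K - 1]) / sds[K]
        rows.append({"K": K, "mean_lnpd": means[K], "sd_lnpd": sds[K], "delta_k": dk})
    df = pd.DataFrame(rows)
    interior = df.dropna(subset=["delta_k"])
    df.attrs["best_k"] = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return df


def assign_membership(fit: StructureFit, threshold: float = 0.75) -> pd.DataFrame:
    """Assign samples to subpopulations by membership probability.

    A sample joins cluster argmax(Q_i) when its maximum membership is at
    least ``threshold`` (the boundary value counts as assigned); below
    the threshold it is labelled ``admixed``.  A threshold-free
    maximum-membership column is always included.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    amax = fit.Q.argmax(axis=1)
    qmax = fit.Q.max(axis=1)
    labels = [
        f"G{k + 1}" if qm >= threshold else "admixed"
        for k, qm in zip(amax, qmax)
    ]
    return pd.DataFrame(
        {
            "sample_id": fit.samples,
            "assignment": labels,
            "max_membership_group": [f"G{k + 1}" for k in amax],
            "max_membership": qmax,
        }
    )


def align_runs(runs: list[StructureFit]) -> list[StructureFit]:
    """Resolve label switching: permute cluster labels of each run to best
    match the first run (greedy matching on Q-column correlation)."""
    if not runs:
        return runs
    K = runs[0].K
    if any(f.K != K for f in runs):
        raise ValueError("all runs must share K")
    ref = runs[0]
    out = [ref]
    for fit in runs[1:]:
        score = np.zeros((K, K))
        for i in range(K):
            for j in range(K):
                score[i, j] = -np.sum((ref.Q[:, i] - fit.Q[:, j]) ** 2)
        perm = np.full(K, -1)
        used_i, used_j = set(), set()
        for _ in range(K):
            best = None
            for i in range(K):
                if i in used_i:
                    continue
                for j in range(K):
                    if j in used_j:
                        continue
                    if best is None or score[i, j] > score[best]:
                        best = (i, j)
            i, j = best
            perm[i] = j
            used_i.add(i)
            used_j.add(j)
        out.append(
            StructureFit(
                K=K, samples=fit.samples, Q=fit.Q[:, perm], P=fit.P[perm, :],
                lnl_trace=fit.lnl_trace, ln_p_d=fit.ln_p_d, seed=fit.seed,
                burn_in=fit.burn_in, n_iter=fit.n_iter, thin=fit.thin,
            )
        )
    return out
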