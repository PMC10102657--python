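"""Model-based structure inference.

``admixture_em`` maximizes the standard admixture likelihood -- each gene
copy of individual i drawn from cluster k with probability q_ik and then
an allele from that cluster's frequency profile -- with an EM algorithm
(multiple seeded restarts, monotone log-likelihood). It deliberately
replaces an MCMC sampler: the target likelihood is the same, the
estimate is the mode rather than a posterior mean.

``evanno_delta_k`` implements the second-order rate-of-change criterion
for choosing K from replicate log-likelihoods: delta K =
mean |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)), with the second difference
taken per replicate before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from germdiv.io_formats import MISSING, MarkerGenotypes, StructureRunTable

__all__ = [
    "AdmixtureFit",
    "DeltaKTable",
    "evanno_delta_k",
    "admixture_em",
    "classify_admixture",
]


@dataclass
class DeltaKTable:
    """Per-K Evanno summary; delta_K is NaN at the endpoints of the K
    range where the second difference is undefined."""

    table: pd.DataFrame  # columns K, mean_L, sd_L, L_prime, abs_L_double_prime, delta_K

    @property
    def best_k(self) -> int:
        valid = self.table.dropna(subset=["delta_K"])
        if valid.empty:
            raise ValueError("delta K undefined everywhere (K range too short)")
        return int(valid.loc[valid["delta_K"].idxmax(), "K"])


@dataclass
class AdmixtureFit:
    k: int
    q: pd.DataFrame  # individuals x K ancestry proportions
    cluster_allele_freqs: dict[str, pd.DataFrame]  # locus -> clusters x alleles
    log_likelihood: float
    trace: list[float]
    converged: bool


# ---------------------------------------------------------------------------
# Evanno delta K


def evanno_delta_k(runs: StructureRunTable) -> DeltaKTable:
    """Evanno et al. delta-K table from replicate log-likelihoods per K."""
    ks = runs.k_values
    if len(ks) < 3:
        raise ValueError("delta K needs >=3 consecutive K values")
    counts = runs.rows.groupby("K").size()
    if (counts < 2).any():
        raise ValueError("delta K needs >=2 replicates per K")
    if counts.nunique() != 1:
        raise ValueError("replicate counts must match across K for pairing")
    # replicate-aligned matrix: rows K, columns replicate rank
    wide = (
        runs.rows.sort_values(["K", "replicate"])
        .assign(rank=lambda d: d.groupby("K").cumcount())
        .pivot(index="K", columns="rank", values="log_likelihood")
        .loc[ks]
        .to_numpy()
    )
    mean_l = wide.mean(axis=1)
    sd_l = wide.std(axis=1, ddof=1)
    l_prime = np.full(len(ks), np.nan)
    l_prime[1:] = mean_l[1:] - mean_l[:-1]
    abs_lpp = np.full(len(ks), np.nan)
    # second difference per replicate, then averaged in absolute value
    if len(ks) >= 3:
        second = wide[2:] - 2 * wide[1:-1] + wide[:-2]
        abs_lpp[1:-1] = np.abs(second).mean(axis=1)
    delta = np.full(len(ks), np.nan)
    interior = ~np.isnan(abs_lpp)
    if (sd_l[interior] == 0).any():
        bad = [k for k, s, inn in zip(ks, sd_l, interior) if inn and s == 0]
        raise ValueError(f"replicate sd is zero at interior K={bad}; delta K undefined")
    delta[interior] = abs_lpp[interior] / sd_l[interior]
    table = pd.DataFrame(
        {
            "K": ks,
            "mean_L": mean_l,
            "sd_L": sd_l,
            "L_prime": l_prime,
            "abs_L_double_prime": abs_lpp,
            "delta_K": delta,
        }
    )
    return DeltaKTable(table)


# ---------------------------------------------------------------------------
# EM admixture


def _encode(geno: MarkerGenotypes) -> tuple[np.ndarray, list[np.ndarray]]:
    """Allele-index encoding: (N, L, 2) indices with -1 for missing, plus
    the allele-code array per locus."""
    n, l = geno.n_individuals, geno.n_loci
    idx = np.full((n, l, 2), -1, dtype=int)
    alleles: list[np.ndarray] = []
    for j in range(l):
        calls = geno.calls[:, j, :]
        scored = calls[:, 0] != MISSING
        uniq = np.unique(calls[scored].ravel())
        alleles.append(uniq)
        lookup = {a: i for i, a in enumerate(uniq)}
        for copy in (0, 1):
            idx[scored, j, copy] = [lookup[a] for a in calls[scored, copy]]
    return idx, alleles


def _log_likelihood(
    idx: np.ndarray, q: np.ndarray, p: list[np.ndarray]
) -> float:
    ll = 0.0
    for j in range(idx.shape[1]):
        for copy in (0, 1):
            a = idx[:, j, copy]
            obs = a >= 0
            if not obs.any():
                continue
            mix = (q[obs] * p[j][:, a[obs]].T).sum(axis=1)
            ll += float(np.log(np.maximum(mix, 1e-300)).sum())
    return ll


def _em_once(
    idx: np.ndarray,
    alleles: list[np.ndarray],
    k: int,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[np.ndarray], list[float], bool]:
    n, l, _ = idx.shape
    q = rng.dirichlet(np.ones(k), size=n)
    p: list[np.ndarray] = []
    for j in range(l):
        counts = np.bincount(idx[:, j, :][idx[:, j, :] >= 0], minlength=len(alleles[j]))
        base = counts + 0.5
        p.append(rng.dirichlet(base, size=k))
    scored_loci = (idx[:, :, 0] >= 0).sum(axis=1)  # loci scored per individual
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        q_num = np.zeros_like(q)
        p_num = [np.zeros_like(pj) for pj in p]
        ll = 0.0
        for j in range(l):
            for copy in (0, 1):
                a = idx[:, j, copy]
                obs = np.where(a >= 0)[0]
                if obs.size == 0:
                    continue
                w = q[obs] * p[j][:, a[obs]].T  # (n_obs, K)
                denom = w.sum(axis=1)
                ll += float(np.log(np.maximum(denom, 1e-300)).sum())
                resp = w / denom[:, None]
                q_num[obs] += resp
                np.add.at(p_num[j].T, a[obs], resp)
        trace.append(ll)
        if len(trace) >= 2:
            gain = trace[-1] - trace[-2]
            if gain < -1e-6:
                raise AssertionError(f"EM log-likelihood decreased by {-gain}")
            if gain < tol:
                converged = True
                break
        q = q_num / np.maximum(2 * scored_loci, 1)[:, None]
        q /= q.sum(axis=1, keepdims=True)
        for j in range(l):
            totals = p_num[j].sum(axis=1, keepdims=True)
            uniform = np.full_like(p[j], 1.0 / p[j].shape[1])
            with np.errstate(invalid="ignore"):
                p[j] = np.where(totals > 0, p_num[j] / np.maximum(totals, 1e-300), uniform)
    return q, p, trace, converged


def admixture_em(
    geno: MarkerGenotypes,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
    n_restarts: int = 5,
) -> AdmixtureFit:
    """Fit the K-cluster admixture model by EM with seeded restarts.

    Keeps the restart with the best final log-likelihood. Non-convergence
    within *max_iter* is flagged (best iterate still returned).
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > geno.n_individuals:
        raise ValueError(f"K={k} exceeds the number of individuals ({geno.n_individuals})")
    idx, alleles = _encode(geno)
    if all(a.size < 2 for a in alleles):
        raise ValueError("no polymorphic locus: the admixture likelihood is flat")
    seeds = np.random.SeedSequence(seed).spawn(max(1, n_restarts))
    best: tuple[float, tuple] | None = None
    for ss in seeds:
        rng = np.random.default_rng(ss)
        q, p, trace, converged = _em_once(idx, alleles, k, max_iter, tol, rng)
        ll = trace[-1]
        if best is None or ll > best[0]:
            best = (ll, (q, p, trace, converged))
    ll, (q, p, trace, converged) = best
    q_frame = pd.DataFrame(
        q, index=geno.individual_ids, columns=[f"cluster{c + 1}" for c in range(k)]
    )
    freqs = {
        locus: pd.DataFrame(
            p[j],
            index=[f"cluster{c + 1}" for c in range(k)],
            columns=[int(a) for a in alleles[j]],
        )
        for j, locus in enumerate(geno.loci)
    }
    return AdmixtureFit(k, q_frame, freqs, float(ll), trace, converged)


def classify_admixture(fit: AdmixtureFit, threshold: float = 0.8) -> pd.Series:
    """Assign each individual to its majority cluster when its ancestry
    proportion reaches *threshold*, else label it "admixed"."""
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0.5, 1], got {threshold}")
    q = fit.q.to_numpy()
    top = q.argmax(axis=1)
    labels = [
        fit.q.columns[t] if q[i, t] >= threshold else "admixed"
        for i, t in enumerate(top)
    ]
    return pd.Series(labels, index=fit.q.index, name="assignment")
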