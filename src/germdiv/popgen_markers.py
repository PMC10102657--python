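"""Population-genetic statistics for codominant SSR genotypes.

Per-locus summaries follow the PowerMarker/GenAlEx conventions: observed
allele count NA, effective allele number NE = 1/sum(p^2), Nei gene
diversity He = 1 - sum(p^2) (uncorrected, so He = 1 - 1/NE holds
exactly), observed heterozygosity Ho, and Botstein's polymorphic
information content PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2.

Between-population structure uses Nei's (1972) standard genetic distance
D = -ln I, UPGMA trees, classical-scaling PCoA, a three-level AMOVA on
gene copies (among populations / among individuals within populations /
within individuals) with Phi fixation indices and permutation tests, and
the Weir-Cockerham theta estimator of pairwise F_ST.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from germdiv.io_formats import MISSING, MarkerGenotypes, TreeNode
from germdiv.quantgen import linkage_to_tree

__all__ = [
    "LocusSummary",
    "DistanceMatrix",
    "AmovaResult",
    "FstMatrix",
    "allele_frequencies",
    "locus_summary",
    "marker_summary_table",
    "nei_distance",
    "upgma_tree",
    "pcoa",
    "amova",
    "pairwise_fst",
    "divergence_label",
]


@dataclass
class LocusSummary:
    locus: str
    na: int
    ne: float
    ho: float
    he: float
    pic: float
    allele_freqs: dict[int, float]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    capped: np.ndarray | None = None  # True where D hit the -ln(0) ceiling

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape must match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class AmovaResult:
    """Three-level AMOVA on gene copies.

    Strata: among populations (AP), among individuals within populations
    (AI), within individuals (WI). Variance components are solved from
    expected mean squares with the unbalanced-design coefficient n_c;
    negative components are truncated to zero (flagged).
    """

    df: dict[str, int]
    ss: dict[str, float]
    components: dict[str, float]
    percent: dict[str, float]
    n_c: float
    phi_st: float
    phi_is: float
    phi_it: float
    truncated: bool = False
    degenerate: bool = False  # all copies identical: Phi undefined
    p_phi_st: float | None = None
    p_phi_is: float | None = None

    STRATA = ("among_populations", "among_individuals_within", "within_individuals")

    @property
    def total_variance(self) -> float:
        return sum(self.components.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s, self.df[s], self.ss[s], self.components[s], self.percent[s])
            for s in self.STRATA
        ]
        return pd.DataFrame(
            rows,
            columns=["source", "df", "SS", "variance_component", "percent"],
        )


@dataclass
class FstMatrix:
    labels: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# allele frequencies and per-locus summaries


def _pop_indices(geno: MarkerGenotypes, subset: str | None) -> np.ndarray:
    if subset is None:
        return np.arange(geno.n_individuals)
    idx = np.array([i for i, p in enumerate(geno.population_labels) if p == subset])
    if idx.size == 0:
        raise KeyError(f"unknown population {subset!r}")
    return idx


def allele_frequencies(
    geno: MarkerGenotypes, locus: str, subset: str | None = None
) -> dict[int, float]:
    """Gene-copy allele frequencies at one locus (each scored individual
    contributes two copies; missing calls leave the denominator)."""
    j = geno.locus_index(locus)
    idx = _pop_indices(geno, subset)
    copies = geno.calls[idx, j, :].ravel()
    copies = copies[copies != MISSING]
    if copies.size == 0:
        raise ValueError(f"all calls missing at locus {locus!r}"
                         + (f" in population {subset!r}" if subset else ""))
    alleles, counts = np.unique(copies, return_counts=True)
    total = counts.sum()
    return {int(a): float(c) / total for a, c in zip(alleles, counts)}


def locus_summary(geno: MarkerGenotypes, locus: str) -> LocusSummary:
    """NA, NE, Ho, He and PIC for one locus."""
    j = geno.locus_index(locus)
    freqs = allele_frequencies(geno, locus)
    scored = geno.calls[:, j, 0] != MISSING
    if scored.sum() < 2:
        raise ValueError(f"locus {locus!r} needs >=2 non-missing calls")
    p = np.array(list(freqs.values()))
    sum_p2 = float(np.sum(p**2))
    he = 1.0 - sum_p2
    ne = 1.0 / sum_p2
    het = geno.calls[scored, j, 0] != geno.calls[scored, j, 1]
    ho = float(het.mean())
    p2 = p**2
    pic = 1.0 - sum_p2 - float(np.sum(np.outer(p2, p2)) - np.sum(p2**2))
    return LocusSummary(locus, int(p.size), ne, ho, he, pic, freqs)


def marker_summary_table(geno: MarkerGenotypes) -> pd.DataFrame:
    """Per-locus summary table plus a mean row (columns NA, NE, Obs Hom,
    Obs Het, Nei, PIC)."""
    rows = []
    for locus in geno.loci:
        s = locus_summary(geno, locus)
        rows.append((s.locus, s.na, s.ne, 1.0 - s.ho, s.ho, s.he, s.pic))
    df = pd.DataFrame(
        rows, columns=["Marker", "NA", "NE", "Obs Hom", "Obs Het", "Nei", "PIC"]
    ).set_index("Marker")
    df.loc["Mean"] = df.mean(axis=0)
    return df


# ---------------------------------------------------------------------------
# Nei distance


def _freq_table(geno: MarkerGenotypes) -> dict[str, dict[str, dict[int, float]]]:
    """pop -> locus -> allele frequency map; loci with no scored call in a
    population are omitted for that population."""
    out: dict[str, dict[str, dict[int, float]]] = {}
    for pop in geno.populations:
        out[pop] = {}
        idx = _pop_indices(geno, pop)
        if geno.missing_mask()[idx].all():
            raise ValueError(f"population {pop!r} has no scored data")
        for locus in geno.loci:
            j = geno.locus_index(locus)
            copies = geno.calls[idx, j, :].ravel()
            copies = copies[copies != MISSING]
            if copies.size == 0:
                continue
            alleles, counts = np.unique(copies, return_counts=True)
            out[pop][locus] = {
                int(a): float(c) / counts.sum() for a, c in zip(alleles, counts)
            }
    return out


def nei_distance(
    geno: MarkerGenotypes, max_distance: float = 10.0
) -> DistanceMatrix:
    """Nei's (1972) standard genetic distance between populations.

    Per pair: I = J_xy / sqrt(J_x J_y) where J_xy, J_x, J_y are the
    arithmetic means over shared loci of sum_a p_xa p_ya, sum_a p_xa^2 and
    sum_a p_ya^2; D = -ln I. Zero identity (fully non-overlapping allele
    sets) is capped at *max_distance* and flagged.
    """
    pops = geno.populations
    if len(pops) < 2:
        raise ValueError("Nei distance needs >=2 populations")
    freqs = _freq_table(geno)
    n = len(pops)
    d = np.zeros((n, n))
    capped = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            fx, fy = freqs[pops[i]], freqs[pops[j]]
            shared = sorted(set(fx) & set(fy))
            if not shared:
                raise ValueError(
                    f"populations {pops[i]!r} and {pops[j]!r} share no scored locus"
                )
            jxy = jx = jy = 0.0
            for locus in shared:
                px, py = fx[locus], fy[locus]
                jxy += sum(px.get(a, 0.0) * py.get(a, 0.0) for a in set(px) | set(py))
                jx += sum(v**2 for v in px.values())
                jy += sum(v**2 for v in py.values())
            m = len(shared)
            identity = (jxy / m) / np.sqrt((jx / m) * (jy / m))
            if identity <= np.exp(-max_distance):
                d[i, j] = d[j, i] = max_distance
                capped[i, j] = capped[j, i] = True
            else:
                d[i, j] = d[j, i] = -np.log(identity)
    return DistanceMatrix(pops, d, capped)


# ---------------------------------------------------------------------------
# trees and ordination


def upgma_tree(d: DistanceMatrix) -> TreeNode:
    """UPGMA (average-linkage) tree; node height is half the merge
    distance, so the output is ultrametric. Labels are sorted
    lexicographically first, which makes tie-breaking deterministic."""
    if np.isnan(d.values).any():
        raise ValueError("distance matrix contains NaN")
    if len(d.labels) < 2:
        raise ValueError("UPGMA needs >=2 labels")
    order = np.argsort(np.array(d.labels, dtype=object))
    labels = [d.labels[i] for i in order]
    mat = d.values[np.ix_(order, order)]
    z = hierarchy.linkage(squareform(mat, checks=False), method="average")
    return linkage_to_tree(z, labels)


def neighbor_joining_tree(d: DistanceMatrix) -> TreeNode:
    """Neighbor-joining alternative for an unrooted-style tree (via
    scikit-bio)."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    sk = nj(SkbioDM(d.values, ids=d.labels))
    from germdiv.io_formats import read_newick

    return read_newick(str(sk).strip())


def pcoa(d: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Principal coordinates analysis (classical metric scaling).

    Double-centers -D^2/2 and eigendecomposes. Returns coordinates on the
    positive axes, all eigenvalues (descending; negatives reported), and
    percent variance over the positive eigenvalues only.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("PCoA needs >=3 labels")
    a = -0.5 * d.values**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10 * max(1.0, abs(eigvals[0]))
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    percent = np.zeros_like(eigvals)
    percent[pos] = 100.0 * eigvals[pos] / eigvals[pos].sum()
    frame = pd.DataFrame(
        coords,
        index=d.labels,
        columns=[f"Axis{i + 1}" for i in range(int(pos.sum()))],
    )
    return frame, eigvals, percent


# ---------------------------------------------------------------------------
# AMOVA


def _copy_distances(geno: MarkerGenotypes) -> np.ndarray:
    """Pairwise distances between all 2N gene copies: number of loci at
    which the two copies carry different alleles, over loci scored in both
    individuals."""
    n, l = geno.n_individuals, geno.n_loci
    copies = geno.calls.transpose(0, 2, 1).reshape(2 * n, l)  # rows 2i, 2i+1
    valid = copies != MISSING
    diff = (copies[:, None, :] != copies[None, :, :]) & valid[:, None, :] & valid[None, :, :]
    return diff.sum(axis=2).astype(float)


def _ss(dmat: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squares of a group of gene copies from pairwise distances."""
    sub = dmat[np.ix_(idx, idx)]
    return float(sub.sum() / 2.0 / idx.size)


def _amova_from_distances(
    dmat: np.ndarray, pop_of_individual: np.ndarray
) -> dict[str, float]:
    """SS partition given the copy-distance matrix and per-individual
    population codes. Copies 2i, 2i+1 belong to individual i."""
    n = pop_of_individual.size
    copy_pop = np.repeat(pop_of_individual, 2)
    all_idx = np.arange(2 * n)
    ss_total = _ss(dmat, all_idx)
    ss_wp = 0.0
    for pop in np.unique(copy_pop):
        ss_wp += _ss(dmat, all_idx[copy_pop == pop])
    ss_wi = float(dmat[2 * np.arange(n), 2 * np.arange(n) + 1].sum() / 2.0)
    return {
        "among_populations": ss_total - ss_wp,
        "among_individuals_within": ss_wp - ss_wi,
        "within_individuals": ss_wi,
    }


def _solve_components(
    ss: dict[str, float], pop_sizes: np.ndarray
) -> tuple[dict[str, float], dict[str, float], dict[str, int], float, bool]:
    p = pop_sizes.size
    n = int(pop_sizes.sum())
    df = {
        "among_populations": p - 1,
        "among_individuals_within": n - p,
        "within_individuals": n,
    }
    ms = {k: ss[k] / df[k] if df[k] > 0 else 0.0 for k in ss}
    copies = 2 * pop_sizes
    m = copies.sum()
    n_c = (m - (copies**2).sum() / m) / (p - 1)
    sigma_wi = ms["within_individuals"]
    sigma_ai = (ms["among_individuals_within"] - sigma_wi) / 2.0
    sigma_ap = (ms["among_populations"] - ms["among_individuals_within"]) / n_c
    truncated = sigma_ai < 0 or sigma_ap < 0
    raw = {
        "among_populations": sigma_ap,
        "among_individuals_within": sigma_ai,
        "within_individuals": sigma_wi,
    }
    comps = {k: max(0.0, v) for k, v in raw.items()}
    return comps, raw, df, float(n_c), truncated


def _phi_stats(comps: dict[str, float]) -> tuple[float, float, float]:
    ap = comps["among_populations"]
    ai = comps["among_individuals_within"]
    wi = comps["within_individuals"]
    total = ap + ai + wi
    if total <= 0:
        return np.nan, np.nan, np.nan
    phi_st = ap / total
    phi_is = ai / (ai + wi) if (ai + wi) > 0 else np.nan
    phi_it = (ap + ai) / total
    return phi_st, phi_is, phi_it


def amova(
    geno: MarkerGenotypes,
    n_permutations: int = 0,
    seed: int | None = None,
) -> AmovaResult:
    """Three-level AMOVA on gene copies for codominant data.

    Squared distances between copies count allelic differences across
    loci (a locus missing in either individual is skipped for that pair),
    which makes the analysis the multi-locus average the fixation indices
    assume. Permutation p-values shuffle individuals among populations
    for Phi_ST and gene copies among individuals within populations for
    Phi_IS.
    """
    pops = geno.populations
    sizes = np.array([geno.population_labels.count(p) for p in pops])
    if len(pops) < 2:
        raise ValueError("AMOVA needs >=2 populations")
    if (sizes < 2).any():
        small = [p for p, s in zip(pops, sizes) if s < 2]
        raise ValueError(f"population(s) of size 1 collapse the design: {small}")
    pop_code = np.array([pops.index(p) for p in geno.population_labels])
    dmat = _copy_distances(geno)
    ss = _amova_from_distances(dmat, pop_code)
    comps, raw, df, n_c, truncated = _solve_components(ss, sizes)
    phi_st, phi_is, phi_it = _phi_stats(comps)
    degenerate = dmat.sum() == 0
    total = sum(comps.values())
    percent = {
        k: (100.0 * v / total if total > 0 else np.nan) for k, v in comps.items()
    }
    result = AmovaResult(
        df=df,
        ss=ss,
        components=comps,
        percent=percent,
        n_c=n_c,
        phi_st=phi_st,
        phi_is=phi_is,
        phi_it=phi_it,
        truncated=truncated,
        degenerate=degenerate,
    )
    if n_permutations > 0 and not degenerate:
        rng = np.random.default_rng(seed)
        # permutation statistics use the untruncated components: clamping
        # negatives to zero creates heavy ties at Phi = 0 under the null
        obs_st = _raw_phi_st(raw)
        obs_is = _raw_phi_is(raw)
        result.p_phi_st = _permute_phi_st(dmat, pop_code, sizes, obs_st, n_permutations, rng)
        result.p_phi_is = _permute_phi_is(geno, pop_code, sizes, obs_is, n_permutations, rng)
    return result


def _raw_phi_st(raw: dict[str, float]) -> float:
    total = sum(raw.values())
    return raw["among_populations"] / total if total > 0 else np.nan


def _raw_phi_is(raw: dict[str, float]) -> float:
    denom = raw["among_individuals_within"] + raw["within_individuals"]
    return raw["among_individuals_within"] / denom if denom > 0 else np.nan


def _permute_phi_st(
    dmat: np.ndarray,
    pop_code: np.ndarray,
    sizes: np.ndarray,
    observed: float,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    if np.isnan(observed):
        return np.nan
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pop_code)
        ss = _amova_from_distances(dmat, perm)
        _, raw, _, _, _ = _solve_components(ss, sizes)
        phi = _raw_phi_st(raw)
        if np.isnan(phi) or phi >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _permute_phi_is(
    geno: MarkerGenotypes,
    pop_code: np.ndarray,
    sizes: np.ndarray,
    observed: float,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    if np.isnan(observed):
        return np.nan
    hits = 0
    calls = geno.calls
    for _ in range(n_perm):
        shuffled = calls.copy()
        for code in range(sizes.size):
            idx = np.where(pop_code == code)[0]
            for j in range(geno.n_loci):
                scored = idx[calls[idx, j, 0] != MISSING]
                if scored.size < 2:
                    continue
                pool = calls[scored, j, :].ravel()
                pool = pool[rng.permutation(pool.size)]
                shuffled[scored, j, :] = pool.reshape(scored.size, 2)
        permuted = MarkerGenotypes(
            geno.individual_ids, geno.population_labels, geno.loci, shuffled
        )
        dmat = _copy_distances(permuted)
        ss = _amova_from_distances(dmat, pop_code)
        _, raw, _, _, _ = _solve_components(ss, sizes)
        phi = _raw_phi_is(raw)
        if np.isnan(phi) or phi >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST


def _wc_components(
    geno: MarkerGenotypes, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[float, float]:
    """Sum of Weir-Cockerham a and a+b+c over loci and alleles for two
    population samples."""
    r = 2
    num = den = 0.0
    for j in range(geno.n_loci):
        groups = []
        for idx in (idx_a, idx_b):
            calls = geno.calls[idx, j, :]
            scored = calls[:, 0] != MISSING
            calls = calls[scored]
            if calls.shape[0] == 0:
                break
            groups.append(calls)
        if len(groups) < 2:
            continue
        alleles = np.unique(np.concatenate([g.ravel() for g in groups]))
        if alleles.size < 2:
            continue
        n_i = np.array([g.shape[0] for g in groups], dtype=float)
        n_bar = n_i.mean()
        if n_bar <= 1:
            continue
        n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
        for allele in alleles:
            p_i = np.array([(g == allele).mean() for g in groups])
            h_i = np.array(
                [((g == allele).sum(axis=1) == 1).mean() for g in groups]
            )
            p_bar = (n_i * p_i).sum() / (r * n_bar)
            s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
            h_bar = (n_i * h_i).sum() / (r * n_bar)
            a = (n_bar / n_c) * (
                s2
                - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar)
                - (r - 1) / r * s2
                - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2
            num += a
            den += a + b + c
    return num, den


def pairwise_fst(geno: MarkerGenotypes) -> FstMatrix:
    """Pairwise Weir-Cockerham theta (multi-locus ratio-of-sums).

    Small negative estimates are reported as computed; they indicate the
    absence of detectable differentiation, not a defect.
    """
    pops = geno.populations
    if len(pops) < 2:
        raise ValueError("pairwise F_ST needs >=2 populations")
    indices = {p: _pop_indices(geno, p) for p in pops}
    n = len(pops)
    theta = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num, den = _wc_components(geno, indices[pops[i]], indices[pops[j]])
            if den == 0:
                raise ValueError(
                    f"populations {pops[i]!r} and {pops[j]!r} share no "
                    "polymorphic scored locus"
                )
            theta[i, j] = theta[j, i] = num / den
    return FstMatrix(pops, theta)


def divergence_label(fst: float) -> str:
    """Wright's qualitative divergence bands for an F_ST value."""
    if fst < 0.05:
        return "little"
    if fst < 0.15:
        return "moderate"
    if fst < 0.25:
        return "great"
    return "very great"
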