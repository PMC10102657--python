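"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is a pure function of its spec (seed included), so tests
and examples are reproducible bit-for-bit. The generators emulate:

* randomized-block phenotype trials with chosen genotypic/error variances
  and an optional genetic correlation structure across traits,
* codominant SSR genotypes under the Balding-Nichols divergence model
  (an interpretable F_ST knob), with optional excess homozygosity via a
  selfing/clonality rate and optional admixed ancestry,
* landrace censuses with Dirichlet dominance structure,
* replicate log-likelihood tables whose mean curve rises steeply to the
  true K and then plateaus, which guarantees a delta-K curvature maximum
  at the true K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from germdiv.io_formats import LandraceCensus, MarkerGenotypes, PhenotypeTrial, StructureRunTable

__all__ = [
    "PhenotypeSimSpec",
    "MarkerSimSpec",
    "CensusSimSpec",
    "simulate_rbd_phenotypes",
    "simulate_ssr_genotypes",
    "simulate_census",
    "simulate_structure_lnp",
]


@dataclass
class PhenotypeSimSpec:
    """Randomized-block trial simulation parameters.

    ``trait_specs`` lists (trait_name, grand_mean, sigma2_g, sigma2_e).
    Block effects are drawn with variance ``block_variance_fraction *
    sigma2_e`` per trait (10% by default).
    """

    n_genotypes: int
    n_blocks: int
    trait_specs: list[tuple[str, float, float, float]]
    genetic_correlation: np.ndarray | None = None
    seed: int = 0
    block_variance_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_genotypes < 1 or self.n_blocks < 1:
            raise ValueError("need >=1 genotype and >=1 block")
        for name, _, s2g, s2e in self.trait_specs:
            if s2g < 0 or s2e < 0:
                raise ValueError(f"negative variance for trait {name!r}")
        if self.genetic_correlation is not None:
            c = np.asarray(self.genetic_correlation, dtype=float)
            t = len(self.trait_specs)
            if c.shape != (t, t):
                raise ValueError("genetic_correlation must be traits x traits")
            if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
                raise ValueError("genetic_correlation must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise ValueError("genetic_correlation is not positive semi-definite")
            self.genetic_correlation = c


@dataclass
class MarkerSimSpec:
    """SSR genotype simulation parameters.

    ``alleles_per_locus`` is either a fixed count or an inclusive (low,
    high) range sampled per locus; the default 3-8 matches typical SSR
    panels. ``divergence_fst`` parameterizes the Balding-Nichols draw of
    population frequencies around a Dirichlet-uniform ancestral profile.
    ``selfing_rate`` is the probability that an individual's second gene
    copy duplicates the first (clonal propagation / selfing shows up as
    excess homozygosity). With ``admixture_alpha`` set, each individual's
    ancestry weights are Dirichlet(alpha, ..., alpha) over populations.
    """

    n_populations: int
    n_individuals_per_pop: int
    n_loci: int
    alleles_per_locus: int | tuple[int, int] = (3, 8)
    divergence_fst: float = 0.0
    selfing_rate: float = 0.0
    admixture_alpha: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo = self.alleles_per_locus if isinstance(self.alleles_per_locus, int) else self.alleles_per_locus[0]
        if lo < 2:
            raise ValueError("alleles_per_locus must be >= 2")
        if not 0 <= self.divergence_fst < 1:
            raise ValueError("divergence_fst must lie in [0, 1)")
        if not 0 <= self.selfing_rate <= 1:
            raise ValueError("selfing_rate must lie in [0, 1]")
        if self.admixture_alpha is not None and self.admixture_alpha <= 0:
            raise ValueError("admixture_alpha must be positive")


@dataclass
class CensusSimSpec:
    """Landrace census simulation: shares ~ Dirichlet(dominance, ...),
    counts ~ multinomial. Small dominance concentrates the census on one
    or a few landraces."""

    n_landraces: int
    dominance: float = 1.0
    total_count: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_landraces < 1:
            raise ValueError("need >=1 landrace")
        if self.dominance <= 0:
            raise ValueError("dominance must be positive")
        if self.total_count < self.n_landraces:
            raise ValueError("total_count must be >= n_landraces")


# ---------------------------------------------------------------------------


def simulate_rbd_phenotypes(spec: PhenotypeSimSpec) -> PhenotypeTrial:
    """value(g, b, t) = grand_mean_t + G_gt + B_bt + e_gbt with genetic
    effects multivariate normal across traits."""
    rng = np.random.default_rng(spec.seed)
    g, r, t = spec.n_genotypes, spec.n_blocks, len(spec.trait_specs)
    corr = spec.genetic_correlation if spec.genetic_correlation is not None else np.eye(t)
    eigval, eigvec = np.linalg.eigh(corr)
    sqrt_corr = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0, None))) @ eigvec.T
    z = rng.standard_normal((g, t))
    sd_g = np.sqrt([s[2] for s in spec.trait_specs])
    genetic = (z @ sqrt_corr.T) * sd_g
    sd_e = np.sqrt([s[3] for s in spec.trait_specs])
    sd_b = np.sqrt(spec.block_variance_fraction) * sd_e
    block = rng.standard_normal((r, t)) * sd_b
    noise = rng.standard_normal((g, r, t)) * sd_e
    genotype_ids = [f"G{i + 1:03d}" for i in range(g)]
    block_ids = [f"B{b + 1}" for b in range(r)]
    rows = []
    for ti, (name, mean, _, _) in enumerate(spec.trait_specs):
        values = mean + genetic[:, None, ti] + block[None, :, ti] + noise[:, :, ti]
        for gi in range(g):
            for bi in range(r):
                rows.append((genotype_ids[gi], block_ids[bi], name, values[gi, bi]))
    return PhenotypeTrial(pd.DataFrame(rows, columns=["genotype", "block", "trait", "value"]))


def _balding_nichols(
    rng: np.random.Generator, ancestral: np.ndarray, fst: float, n_pops: int
) -> np.ndarray:
    """Population allele-frequency draws around an ancestral profile at a
    chosen F_ST."""
    if fst == 0:
        return np.tile(ancestral, (n_pops, 1))
    scale = (1.0 - fst) / fst
    return np.vstack([rng.dirichlet(ancestral * scale) for _ in range(n_pops)])


def simulate_ssr_genotypes(
    spec: MarkerSimSpec,
    ancestry: np.ndarray | None = None,
    return_truth: bool = False,
) -> MarkerGenotypes | tuple[MarkerGenotypes, dict]:
    """Diploid SSR genotypes for n_populations x n_individuals_per_pop
    individuals.

    *ancestry* optionally fixes the (n_individuals, n_populations) weight
    matrix (rows on the simplex), overriding the one-hot / Dirichlet
    default; use it to plant known admixture proportions for recovery
    tests. With ``return_truth`` the generating frequencies and ancestry
    are returned alongside the genotypes.
    """
    rng = np.random.default_rng(spec.seed)
    n_pops, n_per, n_loci = spec.n_populations, spec.n_individuals_per_pop, spec.n_loci
    n = n_pops * n_per
    if isinstance(spec.alleles_per_locus, int):
        allele_counts = np.full(n_loci, spec.alleles_per_locus)
    else:
        lo, hi = spec.alleles_per_locus
        allele_counts = rng.integers(lo, hi + 1, size=n_loci)
    source_pop = np.repeat(np.arange(n_pops), n_per)
    if ancestry is not None:
        w = np.asarray(ancestry, dtype=float)
        if w.shape != (n, n_pops) or not np.allclose(w.sum(axis=1), 1.0):
            raise ValueError("ancestry must be (n_individuals, n_populations) rows on the simplex")
    elif spec.admixture_alpha is not None:
        w = rng.dirichlet(np.full(n_pops, spec.admixture_alpha), size=n)
    else:
        w = np.zeros((n, n_pops))
        w[np.arange(n), source_pop] = 1.0
    ancestral_freqs: list[np.ndarray] = []
    pop_freqs: list[np.ndarray] = []
    allele_codes: list[np.ndarray] = []
    calls = np.zeros((n, n_loci, 2), dtype=int)
    for j in range(n_loci):
        a = int(allele_counts[j])
        ancestral = rng.dirichlet(np.ones(a))
        pf = _balding_nichols(rng, ancestral, spec.divergence_fst, n_pops)
        codes = 100 + 2 * np.arange(a)
        ancestral_freqs.append(ancestral)
        pop_freqs.append(pf)
        allele_codes.append(codes)
        mixed = w @ pf  # (n, a) per-individual sampling frequencies
        cum = np.cumsum(mixed, axis=1)
        first = (rng.random(n)[:, None] > cum[:, :-1]).sum(axis=1)
        second = (rng.random(n)[:, None] > cum[:, :-1]).sum(axis=1)
        selfed = rng.random(n) < spec.selfing_rate
        second = np.where(selfed, first, second)
        pair = np.sort(np.stack([codes[first], codes[second]], axis=1), axis=1)
        calls[:, j, :] = pair
    geno = MarkerGenotypes(
        [f"ind{i + 1:03d}" for i in range(n)],
        [f"pop{p + 1}" for p in source_pop],
        [f"locus{j + 1:02d}" for j in range(n_loci)],
        calls,
    )
    if not return_truth:
        return geno
    truth = {
        "ancestral_freqs": ancestral_freqs,
        "pop_freqs": pop_freqs,
        "allele_codes": allele_codes,
        "ancestry": w,
    }
    return geno, truth


def simulate_census(spec: CensusSimSpec) -> LandraceCensus:
    """Census counts ~ multinomial over Dirichlet(dominance) shares."""
    rng = np.random.default_rng(spec.seed)
    shares = rng.dirichlet(np.full(spec.n_landraces, spec.dominance))
    counts = rng.multinomial(spec.total_count, shares)
    entries = [
        (f"landrace{i + 1:02d}", float(c)) for i, c in enumerate(counts)
    ]
    return LandraceCensus("synthetic-site", entries)


def simulate_structure_lnp(
    true_k: int,
    k_range: tuple[int, int],
    n_replicates: int,
    seed: int = 0,
    noise_sd: float = 2.0,
    base: float = -1200.0,
    steep_gain: float = 60.0,
    plateau_gain: float = 2.0,
) -> StructureRunTable:
    """Replicate log-likelihood table with a piecewise-linear mean curve:
    gain *steep_gain* per K up to the true K, *plateau_gain* beyond.

    The kink at true_k makes it the unique curvature maximum, so the
    delta-K argmax recovers it (up to replicate noise)."""
    k_min, k_max = k_range
    if not (k_min <= true_k - 1 and true_k + 1 <= k_max):
        raise ValueError("k_range must span true_k +- 1")
    if n_replicates < 2:
        raise ValueError("delta K needs >=2 replicates per K (for a standard deviation)")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive (zero sd breaks delta K downstream)")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(k_min, k_max + 1):
        mean = base + steep_gain * min(k, true_k) + plateau_gain * max(0, k - true_k)
        for rep in range(1, n_replicates + 1):
            rows.append((k, rep, mean + rng.normal(0.0, noise_sd)))
    return StructureRunTable(
        pd.DataFrame(rows, columns=["K", "replicate", "log_likelihood"])
    )
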