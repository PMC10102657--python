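"""Quantitative genetics from replicated randomized-block trials.

The estimators are the classical ones used throughout germplasm
characterisation studies: genotype/block/error sums of squares from a
complete randomized block design (RBD), variance components from expected
mean squares (sigma2_g = (MS_g - MS_e)/r), genotypic and phenotypic
coefficients of variation, broad-sense heritability h2 = sigma2_g /
sigma2_p, genetic advance under truncation selection GA = k * h2 *
sigma_p, genotypic/phenotypic correlations from the analogous
cross-product decomposition, and path coefficients solving R p = r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from germdiv.io_formats import PhenotypeTrial, TreeNode

__all__ = [
    "AnovaTable",
    "VarianceComponents",
    "GeneticParams",
    "CorrelationSet",
    "PathResult",
    "rbd_anova",
    "variance_components",
    "genetic_params",
    "genetic_params_table",
    "genotypic_phenotypic_correlations",
    "path_analysis",
    "trait_cluster",
    "trait_pca",
    "linkage_to_tree",
]

#: selection intensity at 5% selected, the conventional constant for
#: genetic-advance estimates
DEFAULT_SELECTION_INTENSITY = 2.06


@dataclass
class AnovaTable:
    """Two-way (genotype + block) ANOVA decomposition for one trait."""

    trait: str
    df: dict[str, int]
    ss: dict[str, float]
    ms: dict[str, float]
    grand_mean: float
    n_genotypes: int
    n_blocks: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (src, self.df[src], self.ss[src], self.ms[src])
            for src in ("genotypes", "blocks", "error")
        ]
        return pd.DataFrame(rows, columns=["source", "df", "SS", "MS"])

    def f_test(self) -> tuple[float, float]:
        """F statistic and p-value for genotype differences."""
        f = self.ms["genotypes"] / self.ms["error"] if self.ms["error"] > 0 else np.inf
        p = float(sps.f.sf(f, self.df["genotypes"], self.df["error"]))
        return float(f), p


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    replications: int
    truncated: bool = False

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_g + self.sigma2_e


@dataclass
class GeneticParams:
    """Burton-Devane coefficients of variation, broad-sense heritability,
    and Johnson genetic advance for one trait."""

    grand_mean: float
    gcv: float  # % of mean
    pcv: float  # % of mean
    h2: float  # % (broad sense)
    ga: float  # trait units
    gam: float  # % of mean
    selection_intensity: float


@dataclass
class CorrelationSet:
    traits: list[str]
    genotypic: pd.DataFrame
    phenotypic: pd.DataFrame
    clamped: pd.DataFrame  # True where |r| > 1 before clamping
    stars_genotypic: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    stars_phenotypic: pd.DataFrame = field(default=None)  # type: ignore[assignment]


@dataclass
class PathResult:
    predictors: list[str]
    direct_effects: np.ndarray
    indirect_effects: np.ndarray  # (i, j): effect of i routed via j = r_ij * p_j
    residual_effect: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.indirect_effects, index=self.predictors, columns=self.predictors
        )
        df["direct"] = self.direct_effects
        return df


# ---------------------------------------------------------------------------
# ANOVA and variance components


def _complete_table(trial: PhenotypeTrial, trait: str) -> pd.DataFrame:
    table = trial.pivot(trait)
    if table.isna().any().any():
        bad = table.stack(future_stack=True)
        bad = bad[bad.isna()].index.tolist()[:3]
        raise ValueError(f"incomplete RBD for trait {trait!r}; first gaps: {bad}")
    return table

def rbd_anova(trial: PhenotypeTrial, trait: str) -> AnovaTable:
    """Genotype/block/error sums of squares for a complete RBD."""
    table = _complete_table(trial, trait)
    g, r = table.shape
    if g < 2 or r < 2:
        raise ValueError(f"RBD ANOVA needs >=2 genotypes and >=2 blocks, got {g}x{r}")
    y = table.to_numpy(dtype=float)
    total = y.sum()
    cf = total**2 / (g * r)
    ss_total = float((y**2).sum() - cf)
    ss_g = float((y.sum(axis=1) ** 2).sum() / r - cf)
    ss_b = float((y.sum(axis=0) ** 2).sum() / g - cf)
    ss_e = max(0.0, ss_total - ss_g - ss_b)
    df = {"genotypes": g - 1, "blocks": r - 1, "error": (g - 1) * (r - 1)}
    ss = {"genotypes": ss_g, "blocks": ss_b, "error": ss_e}
    ms = {k: ss[k] / df[k] for k in ss}
    return AnovaTable(trait, df, ss, ms, float(y.mean()), g, r)


def variance_components(anova: AnovaTable) -> VarianceComponents:
    """Solve sigma2_e = MS_e and sigma2_g = (MS_g - MS_e)/r, truncating a
    negative genotypic estimate to 0 (flagged)."""
    r = anova.n_blocks
    sigma2_e = anova.ms["error"]
    raw = (anova.ms["genotypes"] - sigma2_e) / r
    truncated = raw < 0
    return VarianceComponents(max(0.0, raw), sigma2_e, r, truncated)


def genetic_params(
    vc: VarianceComponents,
    grand_mean: float,
    k: float = DEFAULT_SELECTION_INTENSITY,
) -> GeneticParams:
    """GCV/PCV, broad-sense heritability (percent), and genetic advance."""
    if grand_mean <= 0:
        raise ValueError(f"grand mean must be positive, got {grand_mean}")
    gcv = 100.0 * np.sqrt(vc.sigma2_g) / grand_mean
    pcv = 100.0 * np.sqrt(vc.sigma2_p) / grand_mean
    h2 = 100.0 * vc.sigma2_g / vc.sigma2_p if vc.sigma2_p > 0 else 0.0
    ga = k * (h2 / 100.0) * np.sqrt(vc.sigma2_p)
    gam = 100.0 * ga / grand_mean
    return GeneticParams(grand_mean, float(gcv), float(pcv), float(h2), float(ga), float(gam), k)


def genetic_params_table(
    trial: PhenotypeTrial,
    traits: list[str] | None = None,
    k: float = DEFAULT_SELECTION_INTENSITY,
) -> pd.DataFrame:
    """Per-trait genetic-parameter summary (one column per trait).

    Rows: mean, minimum and maximum of genotype means, SE(m), CV (%),
    GCV, PCV, h2 (%), GA, GAM (%).
    """
    traits = traits if traits is not None else trial.traits
    cols = {}
    for trait in traits:
        an = rbd_anova(trial, trait)
        vc = variance_components(an)
        gp = genetic_params(vc, an.grand_mean, k=k)
        gmeans = trial.pivot(trait).mean(axis=1)
        cols[trait] = {
            "Mean": an.grand_mean,
            "Minimum": float(gmeans.min()),
            "Maximum": float(gmeans.max()),
            "SE(m)": float(np.sqrt(an.ms["error"] / an.n_blocks)),
            "CV": float(100.0 * np.sqrt(an.ms["error"]) / an.grand_mean),
            "GCV": gp.gcv,
            "PCV": gp.pcv,
            "h2": gp.h2,
            "GA": gp.ga,
            "GAM": gp.gam,
        }
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# genotypic / phenotypic correlations


def _cross_products(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Genotype and error mean cross-products of two genotype x block
    tables from the same design."""
    g, r = x.shape
    cf = x.sum() * y.sum() / (g * r)
    sp_total = float((x * y).sum() - cf)
    sp_g = float((x.sum(axis=1) * y.sum(axis=1)).sum() / r - cf)
    sp_b = float((x.sum(axis=0) * y.sum(axis=0)).sum() / g - cf)
    sp_e = sp_total - sp_g - sp_b
    mp_g = sp_g / (g - 1)
    mp_e = sp_e / ((g - 1) * (r - 1))
    return mp_g, mp_e


def genotypic_phenotypic_correlations(
    trial: PhenotypeTrial, traits: list[str] | None = None, alpha: tuple[float, float] = (0.05, 0.01)
) -> CorrelationSet:
    """Genotypic and phenotypic correlation matrices from the analysis of
    covariance between trait pairs.

    For each pair, cov_g = (MP_g - MP_e)/r and cov_p = cov_g + MP_e; the
    correlations divide by the corresponding variance-component products.
    A pair involving a trait with zero genotypic variance has an undefined
    genotypic correlation and is reported as NaN. Estimates beyond +-1
    (possible with component estimators) are clamped and flagged.
    Significance stars use a two-sided t approximation with n_genotypes-2
    degrees of freedom.
    """
    traits = traits if traits is not None else trial.traits
    tables = {t: _complete_table(trial, t).to_numpy(dtype=float) for t in traits}
    shapes = {tables[t].shape for t in traits}
    if len(shapes) != 1:
        raise ValueError("all traits must share the same genotype x block design")
    g, r = shapes.pop()
    n_t = len(traits)
    rg = np.eye(n_t)
    rp = np.eye(n_t)
    clamped = np.zeros((n_t, n_t), dtype=bool)
    var_g, var_p = {}, {}
    for t in traits:
        mp_g, mp_e = _cross_products(tables[t], tables[t])
        var_g[t] = max(0.0, (mp_g - mp_e) / r)
        var_p[t] = var_g[t] + mp_e
    for i in range(n_t):
        for j in range(i + 1, n_t):
            ti, tj = traits[i], traits[j]
            mp_g, mp_e = _cross_products(tables[ti], tables[tj])
            cov_g = (mp_g - mp_e) / r
            cov_p = cov_g + mp_e
            if var_g[ti] <= 0 or var_g[tj] <= 0:
                r_g = np.nan
            else:
                r_g = cov_g / np.sqrt(var_g[ti] * var_g[tj])
            r_p = cov_p / np.sqrt(var_p[ti] * var_p[tj]) if var_p[ti] > 0 and var_p[tj] > 0 else np.nan
            for mat, val in ((rg, r_g), (rp, r_p)):
                if np.isfinite(val) and abs(val) > 1:
                    clamped[i, j] = clamped[j, i] = True
                    val = float(np.clip(val, -1.0, 1.0))
                mat[i, j] = mat[j, i] = val
    dfree = g - 2

    def stars(mat: np.ndarray) -> pd.DataFrame:
        out = np.full(mat.shape, "", dtype=object)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.abs(mat) * np.sqrt(dfree / np.maximum(1e-300, 1 - mat**2))
        pvals = 2 * sps.t.sf(tval, dfree)
        out[pvals < alpha[0]] = "*"
        out[pvals < alpha[1]] = "**"
        np.fill_diagonal(out, "")
        return pd.DataFrame(out, index=traits, columns=traits)

    rg_df = pd.DataFrame(rg, index=traits, columns=traits)
    rp_df = pd.DataFrame(rp, index=traits, columns=traits)
    return CorrelationSet(
        traits,
        rg_df,
        rp_df,
        pd.DataFrame(clamped, index=traits, columns=traits),
        stars(rg),
        stars(rp),
    )


# ---------------------------------------------------------------------------
# path analysis


def path_analysis(
    predictor_correlations: np.ndarray | pd.DataFrame,
    response_correlations: np.ndarray | pd.Series,
    predictors: list[str] | None = None,
    max_condition: float = 1e8,
) -> PathResult:
    """Partition correlations with a response into direct and indirect
    effects by solving R p = r.

    The direct effects are the standardized partial regression
    coefficients; the indirect effect of predictor i routed through j is
    r_ij * p_j; the residual effect is sqrt(1 - sum_i p_i r_i).
    """
    if isinstance(predictor_correlations, pd.DataFrame):
        predictors = list(predictor_correlations.columns)
        R = predictor_correlations.to_numpy(dtype=float)
    else:
        R = np.asarray(predictor_correlations, dtype=float)
    r = np.asarray(response_correlations, dtype=float).ravel()
    n = R.shape[0]
    if R.shape != (n, n) or r.shape != (n,):
        raise ValueError("R must be square and r conformable")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("predictor correlation matrix must be symmetric")
    if predictors is None:
        predictors = [f"x{i + 1}" for i in range(n)]
    if np.linalg.cond(R) > max_condition:
        off = np.abs(R - np.eye(n))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            f"predictor correlation matrix is singular or near-singular; "
            f"most collinear pair: {predictors[i]!r} and {predictors[j]!r} "
            f"(r = {R[i, j]:.4f})"
        )
    p = np.linalg.solve(R, r)
    indirect = R * p[np.newaxis, :]
    np.fill_diagonal(indirect, p)
    residual = float(np.sqrt(max(0.0, 1.0 - float(p @ r))))
    return PathResult(predictors, p, indirect, residual)


# ---------------------------------------------------------------------------
# trait clustering and PCA


def _drop_constant(means: pd.DataFrame) -> pd.DataFrame:
    sd = means.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant traits {constant}", stacklevel=3)
        means = means.drop(columns=constant)
    if means.shape[1] == 0:
        raise ValueError("no variable traits left")
    return means


def linkage_to_tree(z: np.ndarray, labels: list[str]) -> TreeNode:
    """Convert a scipy linkage matrix to a TreeNode dendrogram.

    Internal node height is half the merge distance, so leaf-to-leaf path
    lengths in the tree reproduce cophenetic distances for an
    average-linkage (UPGMA) agglomeration.
    """
    n = len(labels)
    nodes: dict[int, tuple[TreeNode, float]] = {
        i: (TreeNode(label=labels[i]), 0.0) for i in range(n)
    }
    for step, (a, b, dist, _) in enumerate(z):
        height = dist / 2.0
        left, h_left = nodes.pop(int(a))
        right, h_right = nodes.pop(int(b))
        parent = TreeNode(
            children=[(left, height - h_left), (right, height - h_right)]
        )
        nodes[n + step] = (parent, height)
    (root, _), = nodes.values()
    return root


def trait_cluster(
    trial_means: pd.DataFrame, n_clusters: int
) -> tuple[pd.Series, pd.DataFrame, TreeNode]:
    """Ward-linkage agglomerative clustering of genotypes on standardized
    trait means.

    Returns cluster assignments (1-based), a cluster x trait table of
    means on the original scale, and the dendrogram as a TreeNode.
    """
    if n_clusters < 1 or n_clusters > trial_means.shape[0]:
        raise ValueError(f"n_clusters must be in [1, {trial_means.shape[0]}]")
    means = _drop_constant(trial_means)
    z_scores = (means - means.mean(axis=0)) / means.std(axis=0, ddof=1)
    linkage = hierarchy.linkage(z_scores.to_numpy(), method="ward")
    labels = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    assignments = pd.Series(labels, index=means.index, name="cluster")
    cluster_means = trial_means.groupby(assignments).mean()
    cluster_means.index = [f"Cluster-{c}" for c in cluster_means.index]
    tree = linkage_to_tree(linkage, list(means.index))
    return assignments, cluster_means, tree


def trait_pca(
    trial_means: pd.DataFrame,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA on the trait correlation matrix.

    Returns eigenvalues (descending; they sum to the number of traits),
    loadings (traits x components), genotype scores, and percent variance
    per component. Each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    if trial_means.shape[1] < 2 or trial_means.shape[0] < 3:
        raise ValueError("PCA needs >=2 traits and >=3 genotypes")
    sd = trial_means.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant trait(s): {sd[sd == 0].index.tolist()}")
    z = (trial_means - trial_means.mean(axis=0)) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    for c in range(eigvecs.shape[1]):
        if eigvecs[np.argmax(np.abs(eigvecs[:, c])), c] < 0:
            eigvecs[:, c] = -eigvecs[:, c]
    comp_names = [f"PC{i + 1}" for i in range(len(eigvals))]
    loadings = pd.DataFrame(eigvecs, index=trial_means.columns, columns=comp_names)
    scores = pd.DataFrame(
        z.to_numpy() @ eigvecs, index=trial_means.index, columns=comp_names
    )
    percent = 100.0 * eigvals / eigvals.sum()
    return eigvals, loadings, scores, percent
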