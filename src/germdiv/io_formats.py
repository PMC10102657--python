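"""Domain containers and readers/writers for every external format the
pipeline touches.

All tabular formats are plain CSV/whitespace text; trees are Newick.
Marker genotypes are codominant diploid calls (two allele codes per locus
per individual, e.g. fragment sizes in bp). A call is missing only as a
whole pair; partial calls are rejected loudly rather than silently
repaired.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

MISSING = -1  # internal sentinel for a missing allele call

__all__ = [
    "MISSING",
    "LandraceCensus",
    "PhenotypeTrial",
    "MarkerGenotypes",
    "StructureRunTable",
    "TreeNode",
    "read_census",
    "write_census",
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes_genalex",
    "write_genotypes_genalex",
    "read_genotypes_structure",
    "write_genotypes_structure",
    "read_structure_runs",
    "write_structure_runs",
    "write_newick",
    "read_newick",
    "bands_to_genotypes",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class LandraceCensus:
    """Site-labelled landrace counts (or shares treated as counts)."""

    site_label: str
    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate landrace names: {dupes}")
        for name, count in self.entries:
            if count < 0:
                raise ValueError(f"negative count for landrace {name!r}: {count}")
        if not any(c > 0 for _, c in self.entries):
            raise ValueError("census has no entry with positive count")

    @property
    def counts(self) -> np.ndarray:
        return np.array([c for _, c in self.entries], dtype=float)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]


@dataclass
class PhenotypeTrial:
    """Long-format randomized-block trial: one row per
    (genotype, block, trait) observation."""

    records: pd.DataFrame  # columns genotype, block, trait, value

    REQUIRED = ("genotype", "block", "trait", "value")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.records.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        keys = self.records[["genotype", "block", "trait"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate observation for {tuple(dup)}")

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.records["genotype"].unique())

    @property
    def blocks(self) -> list[str]:
        return sorted(self.records["block"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.records["trait"].unique())

    def is_complete(self, trait: str) -> bool:
        """True when every genotype is observed in every block for *trait*."""
        sub = self.records[self.records["trait"] == trait]
        table = sub.pivot(index="genotype", columns="block", values="value")
        return not table.isna().any().any() and table.shape == (
            len(self.genotypes),
            len(self.blocks),
        )

    def pivot(self, trait: str) -> pd.DataFrame:
        """Genotype x block table of values for one trait."""
        sub = self.records[self.records["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present in trial")
        return sub.pivot(index="genotype", columns="block", values="value").sort_index()

    def genotype_means(self, traits: list[str] | None = None) -> pd.DataFrame:
        """Genotype x trait matrix of means over blocks."""
        traits = traits if traits is not None else self.traits
        sub = self.records[self.records["trait"].isin(traits)]
        wide = sub.groupby(["genotype", "trait"])["value"].mean().unstack()
        return wide[traits]


@dataclass
class MarkerGenotypes:
    """Codominant diploid SSR calls.

    ``calls`` has shape (n_individuals, n_loci, 2) with positive integer
    allele codes (fragment sizes) and ``MISSING`` for an absent call.
    """

    individual_ids: list[str]
    population_labels: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=int)
        n, l = len(self.individual_ids), len(self.loci)
        if self.calls.shape != (n, l, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {l}, 2) implied by ids/loci"
            )
        if len(self.population_labels) != n:
            raise ValueError("one population label required per individual")
        a1, a2 = self.calls[..., 0], self.calls[..., 1]
        half = (a1 == MISSING) ^ (a2 == MISSING)
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValueError(
                "half-missing call (missing is all-or-nothing per locus) at "
                f"individual {self.individual_ids[i]!r}, locus {self.loci[j]!r}"
            )
        bad = (self.calls <= 0) & (self.calls != MISSING)
        if bad.any():
            i, j, _ = np.argwhere(bad)[0]
            raise ValueError(
                f"non-positive allele code at individual "
                f"{self.individual_ids[i]!r}, locus {self.loci[j]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(p)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """(n_individuals, n_loci) boolean mask of missing calls."""
        return self.calls[..., 0] == MISSING

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def subset(self, individuals: np.ndarray) -> "MarkerGenotypes":
        idx = np.asarray(individuals)
        return MarkerGenotypes(
            [self.individual_ids[i] for i in idx],
            [self.population_labels[i] for i in idx],
            list(self.loci),
            self.calls[idx],
        )


@dataclass
class StructureRunTable:
    """Replicate log-likelihoods per number of clusters K."""

    rows: pd.DataFrame  # columns K, replicate, log_likelihood

    def __post_init__(self) -> None:
        need = {"K", "replicate", "log_likelihood"}
        if not need <= set(self.rows.columns):
            raise ValueError(f"run table needs columns {sorted(need)}")
        ks = sorted(self.rows["K"].unique())
        if any(int(k) < 1 for k in ks):
            raise ValueError("K values must be >= 1")
        if ks and list(range(int(ks[0]), int(ks[-1]) + 1)) != [int(k) for k in ks]:
            raise ValueError(f"K values must be contiguous, got {ks}")
        if (self.rows.groupby("K").size() < 1).any():
            raise ValueError("every K needs at least one replicate")

    @property
    def k_values(self) -> list[int]:
        return [int(k) for k in sorted(self.rows["K"].unique())]


@dataclass
class TreeNode:
    """Rooted tree with branch lengths; children stored as
    (child, branch_length) pairs."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path length per leaf label."""
        out: dict[str, float] = {}

        def walk(node: "TreeNode", depth: float) -> None:
            if node.is_leaf():
                out[node.label or ""] = depth
            for child, length in node.children:
                walk(child, depth + length)

        walk(self, 0.0)
        return out

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Pairwise leaf-to-leaf path lengths (labels sorted within pair)."""
        dist: dict[tuple[str, str], float] = {}

        def walk(node: "TreeNode") -> dict[str, float]:
            if node.is_leaf():
                return {node.label or "": 0.0}
            below: list[dict[str, float]] = []
            for child, length in node.children:
                sub = walk(child)
                below.append({k: v + length for k, v in sub.items()})
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for la, da in below[i].items():
                        for lb, db in below[j].items():
                            key = (la, lb) if la < lb else (lb, la)
                            dist[key] = da + db
            merged: dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        walk(self)
        return dist


# ---------------------------------------------------------------------------
# censuses


def read_census(path: str, site_label: str | None = None) -> LandraceCensus:
    """Read a landrace census CSV with header ``landrace,count`` (the
    ``landrace,percent`` dialect is accepted; percents are treated as
    counts)."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty census file: {path}")
    cols = [c.strip().lower() for c in df.columns]
    if "landrace" not in cols or not ({"count", "percent"} & set(cols)):
        raise ValueError("census header must be landrace,count or landrace,percent")
    df.columns = cols
    value_col = "count" if "count" in cols else "percent"
    if site_label is None:
        site_label = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    entries = [(str(r["landrace"]), float(r[value_col])) for _, r in df.iterrows()]
    return LandraceCensus(site_label, entries)


def write_census(census: LandraceCensus, path: str) -> None:
    pd.DataFrame(census.entries, columns=["landrace", "count"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# phenotype trials


def read_phenotypes(path: str) -> PhenotypeTrial:
    """Read a long-format trial CSV with header genotype,block,trait,value."""
    df = pd.read_csv(path, dtype={"genotype": str, "block": str, "trait": str})
    return PhenotypeTrial(df)


def write_phenotypes(trial: PhenotypeTrial, path: str) -> None:
    trial.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# marker genotypes


def read_genotypes_genalex(path: str) -> MarkerGenotypes:
    """Read a GenAlEx-style codominant CSV.

    Layout: header row ``individual,population,<locus>,<locus>,...`` with
    two columns per locus, then one row per individual. 0 codes a missing
    allele; a call must be missing as a whole pair.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if any(cell.strip() for cell in r)]
    if not rows:
        raise ValueError(f"empty genotype file: {path}")
    header, body = rows[0], rows[1:]
    allele_cols = header[2:]
    if len(allele_cols) == 0 or len(allele_cols) % 2 != 0:
        raise ValueError(
            f"expected an even, positive number of allele columns, got {len(allele_cols)}"
        )
    loci = [allele_cols[i].strip() for i in range(0, len(allele_cols), 2)]
    ids, pops, calls = [], [], []
    for row in body:
        if len(row) != len(header):
            raise ValueError(f"row length mismatch for {row[0]!r}")
        ids.append(row[0].strip())
        pops.append(row[1].strip())
        pair_row = []
        for j in range(2, len(row), 2):
            try:
                a1, a2 = int(row[j]), int(row[j + 1])
            except ValueError:
                raise ValueError(
                    f"non-integer allele code {row[j]!r}/{row[j + 1]!r} "
                    f"for individual {row[0]!r}"
                ) from None
            pair_row.append(
                (MISSING, MISSING) if a1 == 0 and a2 == 0 else (a1, a2)
            )
            if (a1 == 0) != (a2 == 0):
                raise ValueError(
                    f"half-missing call for individual {row[0]!r} "
                    f"(0 paired with {max(a1, a2)})"
                )
        calls.append(pair_row)
    return MarkerGenotypes(ids, pops, loci, np.array(calls, dtype=int))


def write_genotypes_genalex(geno: MarkerGenotypes, path: str) -> None:
    header = ["individual", "population"]
    for locus in geno.loci:
        header += [locus, locus]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i, ind in enumerate(geno.individual_ids):
            row: list[str] = [ind, geno.population_labels[i]]
            for j in range(geno.n_loci):
                a1, a2 = geno.calls[i, j]
                row += ["0", "0"] if a1 == MISSING else [str(a1), str(a2)]
            writer.writerow(row)


def read_genotypes_structure(path: str) -> MarkerGenotypes:
    """Read STRUCTURE two-row-per-individual format (whitespace separated).

    First line is a locus-name header; each individual then contributes two
    rows ``id pop a_1 ... a_L`` carrying one allele per locus. -9 codes
    missing, and must appear in both rows of an individual at a locus.
    """
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty genotype file: {path}")
    loci = lines[0]
    body = lines[1:]
    if len(body) % 2 != 0:
        raise ValueError("odd number of genotype rows: an individual has one row")
    ids, pops, calls = [], [], []
    for r in range(0, len(body), 2):
        row1, row2 = body[r], body[r + 1]
        if row1[0] != row2[0]:
            raise ValueError(
                f"rows for {row1[0]!r} and {row2[0]!r} are not paired; "
                "each individual needs exactly two consecutive rows"
            )
        for row in (row1, row2):
            if len(row) != 2 + len(loci):
                raise ValueError(f"row length mismatch for individual {row[0]!r}")
        ids.append(row1[0])
        pops.append(row1[1])
        pair_row = []
        for j in range(len(loci)):
            a1, a2 = int(row1[2 + j]), int(row2[2 + j])
            if (a1 == -9) != (a2 == -9):
                raise ValueError(
                    f"half-missing call for individual {row1[0]!r} at locus {loci[j]!r}"
                )
            pair_row.append((MISSING, MISSING) if a1 == -9 else (a1, a2))
        calls.append(pair_row)
    if len(set(ids)) != len(ids):
        raise ValueError("an individual appears in more than two rows")
    return MarkerGenotypes(ids, pops, loci, np.array(calls, dtype=int))


def write_genotypes_structure(geno: MarkerGenotypes, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(geno.loci) + "\n")
        for i, ind in enumerate(geno.individual_ids):
            for copy in (0, 1):
                alleles = [
                    "-9" if geno.calls[i, j, 0] == MISSING else str(geno.calls[i, j, copy])
                    for j in range(geno.n_loci)
                ]
                fh.write(" ".join([ind, geno.population_labels[i]] + alleles) + "\n")


def bands_to_genotypes(
    band_calls: dict[str, dict[str, list[int]]],
    population_labels: dict[str, str] | None = None,
) -> MarkerGenotypes:
    """Convert presence/absence band lists to codominant calls.

    ``band_calls[individual][locus]`` lists the fragment sizes of the bands
    present at that locus. Two bands make a heterozygote, one band a
    homozygote, none a missing call -- the conventional reading of a
    codominant SSR gel. More than two bands is an error (diploid model).
    """
    ids = sorted(band_calls)
    loci = sorted({loc for bands in band_calls.values() for loc in bands})
    calls = np.full((len(ids), len(loci), 2), MISSING, dtype=int)
    for i, ind in enumerate(ids):
        for j, locus in enumerate(loci):
            bands = sorted(band_calls[ind].get(locus, []))
            if len(bands) == 0:
                continue
            if len(bands) == 1:
                calls[i, j] = (bands[0], bands[0])
            elif len(bands) == 2:
                calls[i, j] = (bands[0], bands[1])
            else:
                raise ValueError(
                    f">2 bands for {ind!r} at {locus!r}: not a diploid call"
                )
    pops = [population_labels.get(i, "pop1") if population_labels else "pop1" for i in ids]
    return MarkerGenotypes(ids, pops, loci, calls)


# ---------------------------------------------------------------------------
# structure run tables


def read_structure_runs(path: str) -> StructureRunTable:
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    rename = {"k": "K", "rep": "replicate", "lnp": "log_likelihood", "lnP": "log_likelihood"}
    df = df.rename(columns=rename)
    return StructureRunTable(df[["K", "replicate", "log_likelihood"]])


def write_structure_runs(runs: StructureRunTable, path: str) -> None:
    runs.rows.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trees


def write_newick(tree: TreeNode) -> str:
    """Serialise a tree to Newick with branch lengths."""

    def fmt(x: float) -> str:
        return format(float(x), "g")

    def render(node: TreeNode) -> str:
        if node.is_leaf():
            if not node.label:
                raise ValueError("unlabeled leaf cannot be serialised")
            return node.label
        parts = [f"{render(child)}:{fmt(length)}" for child, length in node.children]
        inner = f"({','.join(parts)})"
        return inner + (node.label or "")

    return render(tree) + ";"


def read_newick(text: str) -> TreeNode:
    """Parse Newick text into a TreeNode (via scikit-bio)."""
    sk = skbio.TreeNode.read(io.StringIO(text))

    def convert(node: skbio.TreeNode) -> TreeNode:
        ours = TreeNode(label=node.name)
        for child in node.children:
            ours.children.append((convert(child), float(child.length or 0.0)))
        return ours

    return convert(sk)
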