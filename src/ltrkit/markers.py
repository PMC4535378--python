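"""Dominant-marker (IRAP/REMAP) diversity analysis.

Band presence/absence matrices are compared with the Jaccard genetic
similarity coefficient GSj = a / (a + b + c) — shared presences over all
bands seen in either individual, double absences carrying no signal —
and clustered by UPGMA on distance 1 - GSj into an ultrametric
dendrogram. Polymorphism summaries follow the dominant-marker
convention: a locus is scorable for a species when at least one of its
individuals shows the band, and polymorphic when it is neither fixed
present nor fixed absent within the species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class MarkerMatrix:
    """Individuals x loci binary band table with species/primer labels."""

    data: pd.DataFrame  # index: individuals, columns: loci, values 0/1
    species: pd.Series  # individual -> species label
    primers: Optional[pd.Series] = None  # locus -> primer label

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("marker matrix must be binary")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate individual ids")
        if not self.data.index.equals(self.species.index):
            self.species = self.species.reindex(self.data.index)
            if self.species.isna().any():
                raise ValueError("species label missing for some individuals")
        if self.primers is None:
            # primer prefix convention: "<primer>_<locus>"
            self.primers = pd.Series(
                [c.split("_")[0] for c in self.data.columns], index=self.data.columns
            )

    @property
    def n_individuals(self) -> int:
        return len(self.data)

    @property
    def n_loci(self) -> int:
        return self.data.shape[1]

    def drop_empty_individuals(self) -> "MarkerMatrix":
        """Remove individuals with zero bands (similarity undefined)."""
        keep = self.data.sum(axis=1) > 0
        if not keep.all():
            dropped = list(self.data.index[~keep])
            warnings.warn(f"dropping bandless individuals: {dropped}")
        return MarkerMatrix(
            data=self.data.loc[keep],
            species=self.species.loc[keep],
            primers=self.primers,
        )

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "species", self.species)
        out.to_csv(path, sep="\t", index_label="individual")

    @classmethod
    def from_tsv(cls, path) -> "MarkerMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="individual")
        species = frame.pop("species")
        return cls(data=frame.astype(int), species=species)


def jaccard_matrix(matrix: MarkerMatrix) -> pd.DataFrame:
    """Pairwise Jaccard similarity GSj = a / (a + b + c).

    Pairs with no band in either individual (a + b + c = 0) are
    undefined and returned as NaN with a warning.
    """
    if matrix.n_individuals < 2:
        raise ValueError("need at least two individuals")
    x = matrix.data.to_numpy(dtype=np.int64)
    shared = x @ x.T  # a
    totals = x.sum(axis=1)
    union = totals[:, None] + totals[None, :] - shared  # a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, shared / np.maximum(union, 1), np.nan)
    if (union == 0).any():
        bad = [
            (matrix.data.index[i], matrix.data.index[j])
            for i, j in zip(*np.where(union == 0))
            if i < j
        ]
        warnings.warn(f"undefined Jaccard similarity for band-free pairs: {bad}")
    return pd.DataFrame(sim, index=matrix.data.index, columns=matrix.data.index)


@dataclass
class DendrogramNode:
    """Node of a rooted ultrametric dendrogram (heights in distance/2 units)."""

    name: Optional[str] = None
    height: float = 0.0
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self, parent_height: Optional[float] = None) -> str:
        if self.is_leaf:
            body = self.name
        else:
            body = "(" + ",".join(c.to_newick(self.height) for c in self.children) + ")"
        if parent_height is None:
            return body + ";"
        return f"{body}:{_fmt(parent_height - self.height)}"


def _fmt(x: float) -> str:
    s = f"{x:.10f}".rstrip("0").rstrip(".")
    return s if s else "0"


def upgma(distances: pd.DataFrame) -> DendrogramNode:
    """UPGMA dendrogram from a symmetric distance matrix.

    Cluster distances are size-weighted arithmetic means; each merge sits
    at half the merge distance so root-to-leaf path lengths are equal.
    Ties are broken by the lexicographically smallest member id of the
    candidate pair.
    """
    d = distances.to_numpy(dtype=float).copy()
    labels = list(distances.index)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    if np.isnan(d).any():
        pairs = [
            (labels[i], labels[j]) for i, j in zip(*np.where(np.isnan(d))) if i < j
        ]
        raise ValueError(f"NaN distances for pairs: {pairs}")
    if not np.allclose(d, d.T) or (np.diag(d) != 0).any() or (d < 0).any():
        raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")

    clusters: dict[int, DendrogramNode] = {
        i: DendrogramNode(name=lab) for i, lab in enumerate(labels)
    }
    sizes = {i: 1 for i in range(n)}
    min_leaf = {i: lab for i, lab in enumerate(labels)}
    active = set(range(n))
    dist = {(min(i, j), max(i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}

    next_id = n
    while len(active) > 1:
        # smallest distance; ties by lexicographic smallest member ids
        best = min(
            ((i, j) for (i, j) in dist if i in active and j in active),
            key=lambda ij: (
                dist[ij],
                min(min_leaf[ij[0]], min_leaf[ij[1]]),
                max(min_leaf[ij[0]], min_leaf[ij[1]]),
            ),
        )
        i, j = best
        dij = dist[best]
        height = dij / 2.0
        # deterministic printing: child with smallest leaf id first
        first, second = sorted((i, j), key=lambda c: min_leaf[c])
        node = DendrogramNode(height=height, children=[clusters[first], clusters[second]])
        new = next_id
        next_id += 1
        for k in active - {i, j}:
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(min(new, k), max(new, k))] = dnew
        active -= {i, j}
        active.add(new)
        clusters[new] = node
        sizes[new] = sizes[i] + sizes[j]
        min_leaf[new] = min(min_leaf[i], min_leaf[j])
    return clusters[next_id - 1]


def upgma_from_similarity(similarity: pd.DataFrame) -> DendrogramNode:
    """Cluster on distance 1 - GSj."""
    dist = 1.0 - similarity
    np.fill_diagonal(dist.values, 0.0)
    return upgma(dist)


def is_ultrametric(node: DendrogramNode, tol: float = 1e-9) -> bool:
    """True if all root-to-leaf branch-length sums agree within ``tol``."""
    depths: list[float] = []

    def walk(n: DendrogramNode, acc: float) -> None:
        if n.is_leaf:
            depths.append(acc)
        for c in n.children:
            walk(c, acc + (n.height - c.height))

    walk(node, 0.0)
    return max(depths) - min(depths) <= tol if depths else True


def polymorphism_stats(matrix: MarkerMatrix) -> pd.DataFrame:
    """Scorable and polymorphic band counts per species x primer.

    Returns one row per (species, primer) plus per-species averages
    across primers (primer = "ALL"). Species with a single individual
    have undefined polymorphism (NaN, flagged by a warning).
    """
    frames = []
    for sp in sorted(matrix.species.unique()):
        sub = matrix.data.loc[matrix.species == sp]
        single = len(sub) < 2
        if single:
            warnings.warn(f"species {sp} has < 2 individuals; polymorphism undefined")
        for primer in sorted(matrix.primers.unique()):
            loci = matrix.primers.index[matrix.primers == primer]
            block = sub[loci]
            present = block.sum(axis=0)
            scorable = int((present > 0).sum())
            if single:
                poly = np.nan
                pct = np.nan
            else:
                poly = int(((present > 0) & (present < len(block))).sum())
                pct = 100.0 * poly / scorable if scorable else 0.0
            frames.append(
                {
                    "species": sp,
                    "primer": primer,
                    "scorable_bands": scorable,
                    "polymorphic_bands": poly,
                    "pct_polymorphic": pct,
                }
            )
    table = pd.DataFrame(frames)
    means = (
        table.groupby("species", as_index=False)
        .agg(
            scorable_bands=("scorable_bands", "mean"),
            polymorphic_bands=("polymorphic_bands", "mean"),
            pct_polymorphic=("pct_polymorphic", "mean"),
        )
        .assign(primer="ALL")
    )
    return pd.concat([table, means], ignore_index=True)[
        ["species", "primer", "scorable_bands", "polymorphic_bands", "pct_polymorphic"]
    ]


def read_band_calls(
    fragment_sizes: dict[str, Sequence[float]],
    size_tolerance: float = 0.02,
    species: Optional[dict[str, str]] = None,
) -> MarkerMatrix:
    """Merge per-individual fragment size lists into a binary locus matrix.

    Sizes across individuals are pooled, sorted, and merged into one
    locus while each size lies within ``size_tolerance`` (fractional) of
    the locus seed size. Emulates manual gel scoring of shared bands.
    """
    all_sizes = []
    for ind, sizes in fragment_sizes.items():
        for s in sizes:
            if s <= 0:
                raise ValueError(f"non-positive fragment size for {ind}")
            all_sizes.append(float(s))
    loci_seeds: list[float] = []
    for s in sorted(set(all_sizes)):
        if not loci_seeds or s > loci_seeds[-1] * (1 + size_tolerance):
            loci_seeds.append(s)
    individuals = list(fragment_sizes)
    data = np.zeros((len(individuals), len(loci_seeds)), dtype=int)
    for i, ind in enumerate(individuals):
        for s in fragment_sizes[ind]:
            for j, seed in enumerate(loci_seeds):
                if seed <= s <= seed * (1 + size_tolerance):
                    data[i, j] = 1
                    break
    columns = [f"B_{int(round(seed))}" for seed in loci_seeds]
    species_series = pd.Series(
        [species.get(ind, "NA") if species else "NA" for ind in individuals],
        index=individuals,
    )
    frame = pd.DataFrame(data, index=individuals, columns=columns)
    return MarkerMatrix(data=frame, species=species_series)
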