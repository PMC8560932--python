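"""Relationship matrices, clustering, trees and clade designation.

The genetic distance used throughout is the Euclidean distance between rows
of the additive (genomic) relationship matrix computed from centred marker
genotypes (VanRaden method 1).  Clades can come from a dendrogram cut, an
imported newick tree, or a manual table; downstream nomenclature and
recombinant logic only need the resulting partition.
"""

from __future__ import annotations

import io
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .variant_core import ALT, MISSING, REF, GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "Dendrogram",
    "CladePartition",
    "additive_relationship",
    "distance_from_A",
    "hierarchical_cluster",
    "neighbor_joining",
    "cut_clades",
    "clades_for_haplotypes",
    "read_newick",
    "write_newick",
    "roman",
]


@dataclass
class RelationshipMatrix:
    """Additive relationship matrix A with its normalisation bookkeeping."""

    values: np.ndarray
    samples: list[str]
    n_markers: int
    denom: float

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.samples, columns=self.samples).to_csv(
            path, sep="\t"
        )


def additive_relationship(m) -> RelationshipMatrix:
    """A = WW' / (2 sum p(1-p)) with markers centred by 2p-1 (VanRaden 1).

    Calls are coded -1 (REF) / +1 (ALT); missing cells are imputed to the
    marker mean.  Monomorphic markers (after imputation) are an error — they
    must be filtered upstream.
    """
    if isinstance(m, GenotypeMatrix):
        calls, samples = m.calls, list(m.samples)
    else:
        calls, samples = np.asarray(m), None
    if samples is None:
        samples = [f"s{i}" for i in range(calls.shape[1])]
    # samples x markers, coded -1/+1 with NaN for missing
    M = np.where(calls == ALT, 1.0, np.where(calls == REF, -1.0, np.nan)).T
    if M.size == 0:
        raise ValueError("empty genotype matrix")
    col_mean = np.nanmean(M, axis=0)
    if np.isnan(col_mean).any():
        raise ValueError("marker with no called samples")
    p = (col_mean + 1.0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        bad = int(np.argwhere((p <= 0) | (p >= 1))[0][0])
        raise ValueError(f"monomorphic marker at column {bad}; filter sites first")
    idx = np.where(np.isnan(M))
    M[idx] = np.take(col_mean, idx[1])
    W = M - (2.0 * p - 1.0)
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    A = (W @ W.T) / denom
    return RelationshipMatrix(A, samples, calls.shape[0], denom)


def distance_from_A(A: RelationshipMatrix) -> DistanceMatrix:
    """Euclidean distance between rows of A; zero iff rows are identical."""
    d = squareform(pdist(A.values, metric="euclidean"), checks=False)
    return DistanceMatrix(d, ids=A.samples)


@dataclass
class Dendrogram:
    """Agglomerative merge tree (scipy linkage encoding) with leaf labels."""

    Z: np.ndarray
    labels: list[str]


def hierarchical_cluster(D, method: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a distance matrix (complete/average/single)."""
    if method not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage {method!r}")
    if not isinstance(D, DistanceMatrix):
        D = DistanceMatrix(np.asarray(D))
    if D.shape[0] < 2:
        raise ValueError("need at least 2 observations to cluster")
    Z = linkage(D.condensed_form(), method=method)
    return Dendrogram(Z, list(D.ids))


def neighbor_joining(D) -> TreeNode:
    """Saitou–Nei neighbor joining; negative branch lengths clamped to 0."""
    if not isinstance(D, DistanceMatrix):
        D = DistanceMatrix(np.asarray(D))
    if D.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = nj(D, neg_as_zero=False)
    negatives = [n for n in tree.traverse() if n.length is not None and n.length < 0]
    if negatives:
        warnings.warn(
            f"clamped {len(negatives)} negative branch length(s) to 0", stacklevel=2
        )
        for n in negatives:
            n.length = 0.0
    return tree


def roman(n: int) -> str:
    if n < 1:
        raise ValueError("roman numerals start at 1")
    vals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
        (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for v, s in vals:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


@dataclass
class CladePartition:
    """Nested major-clade (roman) / subclade (integer) labels per unit."""

    units: list[str]
    major: dict[str, str]
    sub: dict[str, int]
    source: str = "dendrogram-cut"

    def __post_init__(self) -> None:
        # each subclade must sit inside exactly one major-clade
        seen: dict[int, str] = {}
        for u in self.units:
            s, mjr = self.sub[u], self.major[u]
            if seen.setdefault(s, mjr) != mjr:
                raise ValueError(f"subclade {s} spans multiple major-clades")

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {"unit": u, "major_clade": self.major[u], "subclade": self.sub[u]}
                for u in self.units
            ]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, source: str = "manual table") -> "CladePartition":
        df = pd.read_csv(path, sep="\t")
        units = [str(u) for u in df["unit"]]
        return cls(
            units,
            dict(zip(units, df["major_clade"].astype(str))),
            dict(zip(units, df["subclade"].astype(int))),
            source=source,
        )


def cut_clades(dendro: Dendrogram, k_major: int = 3, k_sub: int = 15) -> CladePartition:
    """Cut one dendrogram at ``k_major`` and the nested ``k_sub`` groups.

    Major clades are labelled I, II, III… by descending member count (ties by
    smallest member label); subclades are numbered 1..k_sub consecutively in
    that major order, largest first within each major clade.
    """
    n = len(dendro.labels)
    if k_sub < k_major:
        raise ValueError("k_sub must be >= k_major (nested cut)")
    if not (1 <= k_major and k_sub <= n):
        raise ValueError("require 1 <= k_major <= k_sub <= n")
    def _cut(k: int) -> np.ndarray:
        if k == n:  # scipy's cut_tree degenerates at n_clusters == n
            return np.arange(n)
        return cut_tree(dendro.Z, n_clusters=k)[:, 0]

    raw_major, raw_sub = _cut(k_major), _cut(k_sub)
    labels = dendro.labels

    def _ordered(raw: np.ndarray) -> list[int]:
        groups = defaultdict(list)
        for lbl, g in zip(labels, raw):
            groups[int(g)].append(lbl)
        return sorted(groups, key=lambda g: (-len(groups[g]), min(groups[g])))

    major_order = _ordered(raw_major)
    major_name = {g: roman(i + 1) for i, g in enumerate(major_order)}

    # nest subclades within majors, then number across majors in major order
    sub_members = defaultdict(list)
    sub_major: dict[int, int] = {}
    for lbl, g_m, g_s in zip(labels, raw_major, raw_sub):
        sub_members[int(g_s)].append(lbl)
        sub_major[int(g_s)] = int(g_m)
    sub_number: dict[int, int] = {}
    counter = 1
    for g_m in major_order:
        subs = [s for s in sub_members if sub_major[s] == g_m]
        subs.sort(key=lambda s: (-len(sub_members[s]), min(sub_members[s])))
        for s in subs:
            sub_number[s] = counter
            counter += 1
    major = {lbl: major_name[int(g)] for lbl, g in zip(labels, raw_major)}
    sub = {lbl: sub_number[int(g)] for lbl, g in zip(labels, raw_sub)}
    return CladePartition(list(labels), major, sub, source="dendrogram-cut")


def clades_for_haplotypes(partition, sample_clades: CladePartition) -> CladePartition:
    """Lift a sample-level clade partition to haplotype units by carrier majority.

    Ties break toward the smaller label so the lift is deterministic.  Using
    one sample-level clustering for both subunits keeps the major-clade labels
    of the x and y partitions comparable.
    """
    major: dict[str, str] = {}
    sub: dict[str, int] = {}
    for hap_id in partition.haplotypes:
        members = partition.members(hap_id)
        if not members:
            raise ValueError(f"haplotype {hap_id!r} has no carriers")
        mv = Counter(sample_clades.major[s] for s in members)
        sv = Counter(sample_clades.sub[s] for s in members)
        major[hap_id] = min(
            (m for m, c in mv.items() if c == max(mv.values())),
        )
        sub[hap_id] = min(s for s, c in sv.items() if c == max(sv.values()))
    # enforce nesting: a subclade label must map to one major label; if the
    # majority votes disagree, follow the subclade's own majority major
    sub_major: dict[int, Counter] = defaultdict(Counter)
    for h in partition.haplotypes:
        sub_major[sub[h]][major[h]] += 1
    fix = {
        s: min(m for m, c in v.items() if c == max(v.values())) for s, v in sub_major.items()
    }
    major = {h: fix[sub[h]] for h in major}
    return CladePartition(
        list(partition.haplotypes), major, sub, source=sample_clades.source
    )


def read_newick(text: str) -> TreeNode:
    """Parse newick; rejects duplicate tip labels."""
    tree = TreeNode.read(io.StringIO(text))
    tips = [t.name for t in tree.tips()]
    dupes = [t for t, c in Counter(tips).items() if t is not None and c > 1]
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    return tree


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip() + "\n"
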