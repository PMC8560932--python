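"""Exact-match molecular haplotype grouping, nomenclature and recombinant calls.

Samples sharing identical allele vectors over a region scope share a
molecular haplotype.  Haplotype names follow the subclade-letter scheme used
for HMW-glutenin alleles (``Dx1a`` = first x-subunit haplotype of subclade 1,
ordered by carrier count); combined locus haplotypes pair the two subunits
(``x1a+y1b``).  Because the x and y genes are tightly linked, a combined
haplotype whose subunits sit in different major clades, as a minority pairing,
is evidence of a rare historical crossover between the genes.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_core import MISSING, GenotypeMatrix

__all__ = [
    "AMBIGUOUS",
    "HaplotypePartition",
    "NomenclatureTable",
    "RecombinantCall",
    "group_haplotypes",
    "combine_subunits",
    "flank_consistency",
    "assign_names",
    "detect_recombinants",
]

AMBIGUOUS = "AMBIGUOUS"


@dataclass
class HaplotypePartition:
    """Assignment of samples to exact-match haplotypes over a region scope."""

    scope: tuple[str, ...]
    samples: list[str]
    haplotypes: dict[str, np.ndarray]  # haplotype id -> allele vector
    assignment: dict[str, str]  # sample -> haplotype id or AMBIGUOUS
    #: for combined partitions: haplotype id -> (x id, y id)
    subunit_ids: dict[str, tuple[str, str]] | None = None

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def member_counts(self) -> Counter:
        c = Counter(h for h in self.assignment.values() if h != AMBIGUOUS)
        for h in self.haplotypes:
            c.setdefault(h, 0)
        return c

    def members(self, hap_id: str) -> list[str]:
        return sorted(s for s, h in self.assignment.items() if h == hap_id)

    def ambiguous_samples(self) -> list[str]:
        return sorted(s for s, h in self.assignment.items() if h == AMBIGUOUS)

    def to_tsv(self, path, names: dict[str, str] | None = None) -> None:
        rows = []
        counts = self.member_counts()
        for hap_id, vec in self.haplotypes.items():
            rows.append(
                {
                    "haplotype": hap_id,
                    "name": (names or {}).get(hap_id, ""),
                    "members": counts[hap_id],
                    "samples": ",".join(self.members(hap_id)),
                    "alleles": "".join("RA?"[v] if v in (0, 1) else "." for v in vec),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _canonical_order(groups: dict[bytes, list[str]]) -> list[bytes]:
    """Descending member count, ties broken by lexicographic smallest member."""
    return sorted(groups, key=lambda k: (-len(groups[k]), min(groups[k])))


def group_haplotypes(m: GenotypeMatrix, scope) -> HaplotypePartition:
    """Partition samples by exact vector equality over ``scope`` regions.

    Fully called samples define the haplotypes.  A sample with missing calls
    is adopted by a haplotype iff its called positions are consistent with
    exactly one existing haplotype; otherwise it is AMBIGUOUS.  Ids are stable
    under sample and site reordering.
    """
    scope = tuple(scope) if not isinstance(scope, str) else (scope,)
    if len(scope) == 0:
        raise ValueError("empty scope")
    sub = m.restrict_regions(scope)
    if sub.n_sites == 0:
        raise ValueError(f"no sites in scope {scope}")
    calls = sub.calls  # (n_sites, n_samples)
    complete = ~(calls == MISSING).any(axis=0)
    groups: dict[bytes, list[str]] = defaultdict(list)
    for j, sample in enumerate(sub.samples):
        if complete[j]:
            groups[calls[:, j].tobytes()].append(sample)

    assignment: dict[str, str] = {}
    vectors = {k: np.frombuffer(k, dtype=np.int8).copy() for k in groups}
    for j, sample in enumerate(sub.samples):
        if complete[j]:
            continue
        v = calls[:, j]
        called = v != MISSING
        compatible = [k for k, hv in vectors.items() if np.array_equal(v[called], hv[called])]
        if len(compatible) == 1:
            groups[compatible[0]].append(sample)
            assignment[sample] = "pending"
        else:
            assignment[sample] = AMBIGUOUS

    order = _canonical_order(groups)
    ids = {k: f"h{i + 1:02d}" for i, k in enumerate(order)}
    haplotypes = {ids[k]: vectors[k] for k in order}
    for k, members in groups.items():
        for s in members:
            assignment[s] = ids[k]
    for s in sub.samples:
        assignment.setdefault(s, AMBIGUOUS)
    return HaplotypePartition(scope, list(sub.samples), haplotypes, assignment)


def combine_subunits(px: HaplotypePartition, py: HaplotypePartition) -> HaplotypePartition:
    """Combined locus haplotype = (x haplotype, y haplotype) pair per sample."""
    if set(px.samples) != set(py.samples):
        raise ValueError("sample universes differ between subunit partitions")
    pairs: dict[tuple[str, str], list[str]] = defaultdict(list)
    assignment: dict[str, str] = {}
    for s in px.samples:
        hx, hy = px.assignment[s], py.assignment[s]
        if AMBIGUOUS in (hx, hy):
            assignment[s] = AMBIGUOUS
        else:
            pairs[(hx, hy)].append(s)
    order = sorted(pairs, key=lambda k: (-len(pairs[k]), min(pairs[k])))
    ids = {k: f"c{i + 1:02d}" for i, k in enumerate(order)}
    haplotypes = {
        ids[(hx, hy)]: np.concatenate([px.haplotypes[hx], py.haplotypes[hy]])
        for (hx, hy) in order
    }
    for k, members in pairs.items():
        for s in members:
            assignment[s] = ids[k]
    return HaplotypePartition(
        tuple(px.scope) + tuple(py.scope),
        list(px.samples),
        haplotypes,
        assignment,
        subunit_ids={ids[k]: k for k in order},
    )


def flank_consistency(p_coding: HaplotypePartition, p_full: HaplotypePartition) -> int:
    """Haplotypes added by widening the scope (e.g. coding -> coding+flanks).

    Widening the scope can only split groups, so the difference is >= 0 on
    fully called data.
    """
    if set(p_coding.samples) != set(p_full.samples):
        raise ValueError("partitions cover different samples")
    if not set(p_coding.scope) <= set(p_full.scope):
        raise ValueError("p_full scope must contain p_coding scope")
    return p_full.n_haplotypes - p_coding.n_haplotypes


@dataclass
class NomenclatureTable:
    """Haplotype id -> field-style name, e.g. ``Dx1a`` or ``x1a+y1b``."""

    subunit: str
    names: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, hap_id: str) -> str:
        return self.names[hap_id]

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [{"haplotype": h, "name": n} for h, n in sorted(self.names.items())]
        ).to_csv(path, sep="\t", index=False)


def _letters():
    import itertools
    import string

    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_lowercase, repeat=size):
            yield "".join(combo)


def assign_names(p: HaplotypePartition, clades, subunit: str) -> NomenclatureTable:
    """Letter naming within subclades: canonical carrier-count order.

    ``clades`` is a :class:`~gluhap.phylo.CladePartition` over this
    partition's haplotype ids.  Letters restart within each subclade and carry
    no meaning across subclades.
    """
    for h in p.haplotypes:
        if h not in clades.sub:
            raise ValueError(f"haplotype {h!r} lacks a subclade assignment")
    counts = p.member_counts()
    by_sub: dict[int, list[str]] = defaultdict(list)
    for h in p.haplotypes:
        by_sub[clades.sub[h]].append(h)
    names: dict[str, str] = {}
    for sub_id, haps in by_sub.items():
        haps.sort(key=lambda h: (-counts[h], min(p.members(h), default="~")))
        for h, letter in zip(haps, _letters()):
            names[h] = f"D{subunit}{sub_id}{letter}"
    return NomenclatureTable(subunit, names)


def combined_names(
    combined: HaplotypePartition, nx: NomenclatureTable, ny: NomenclatureTable
) -> NomenclatureTable:
    """``x{n}{a}+y{m}{b}`` names for combined haplotypes from subunit names."""
    if combined.subunit_ids is None:
        raise ValueError("partition is not a combined partition")
    # subunit names look like Dx1a / Dy1b -> combined x1a+y1b
    names = {
        cid: f"x{nx[hx][2:]}+y{ny[hy][2:]}" for cid, (hx, hy) in combined.subunit_ids.items()
    }
    return NomenclatureTable("combined", names)


@dataclass(frozen=True)
class RecombinantCall:
    sample: str
    x_haplotype: str
    x_major: str
    y_haplotype: str
    y_major: str
    expected_y_major: str
    note: str = ""


def detect_recombinants(
    combined: HaplotypePartition,
    x_clades,
    y_clades,
    minority_fraction: float = 0.5,
) -> list[RecombinantCall]:
    """Flag minority x/y pairings whose subunit major-clades disagree.

    For each x haplotype the majority y major-clade among its carriers defines
    the expected linkage; a pairing is flagged when the two subunit
    major-clades differ and the pairing carries fewer than
    ``minority_fraction`` of that x haplotype's carriers.  The symmetric check
    is run from the y side and the union reported.  The two clade partitions
    must share a comparable label universe (e.g. both derived from one
    sample-level clustering).
    """
    if combined.subunit_ids is None:
        raise ValueError("combined partition required (use combine_subunits)")
    counts = combined.member_counts()
    pair_count = {pair: counts[cid] for cid, pair in combined.subunit_ids.items()}
    pair_id = {pair: cid for cid, pair in combined.subunit_ids.items()}

    flagged: dict[str, RecombinantCall] = {}

    def _majority(side: int) -> dict[str, str | None]:
        """Per anchor haplotype on ``side``, majority partner major-clade (None on tie)."""
        votes: dict[str, Counter] = defaultdict(Counter)
        for p, c in pair_count.items():
            partner = p[1 - side]
            clade = (y_clades if side == 0 else x_clades).major[partner]
            votes[p[side]][clade] += c
        out: dict[str, str | None] = {}
        for anchor, v in votes.items():
            top = v.most_common()
            out[anchor] = None if len(top) > 1 and top[0][1] == top[1][1] else top[0][0]
        return out

    expected_y_of_x = _majority(0)  # x haplotype -> majority y major-clade
    expected_x_of_y = _majority(1)

    def _scan(side: int):
        totals: Counter = Counter()
        for p, c in pair_count.items():
            totals[p[side]] += c
        expected = expected_y_of_x if side == 0 else expected_x_of_y
        for p, c in pair_count.items():
            hx, hy = p
            cx, cy = x_clades.major[hx], y_clades.major[hy]
            exp = expected[p[side]]
            if exp is None or cx == cy:
                continue  # tied majority or concordant pairing
            if c >= minority_fraction * totals[p[side]]:
                continue
            exp_y = expected_y_of_x[hx] if expected_y_of_x[hx] is not None else cx
            for sample in combined.members(pair_id[p]):
                flagged.setdefault(
                    sample,
                    RecombinantCall(
                        sample,
                        hx,
                        cx,
                        hy,
                        cy,
                        exp_y,
                        note=(
                            f"minority pairing ({c}/{totals[p[side]]} carriers of "
                            f"{'x' if side == 0 else 'y'} haplotype {p[side]}); "
                            f"majority partner major-clade {exp}"
                        ),
                    ),
                )

    _scan(0)
    _scan(1)
    return sorted(flagged.values(), key=lambda rc: rc.sample)


def recombinants_to_tsv(calls: list[RecombinantCall], path) -> None:
    pd.DataFrame([vars(c) for c in calls]).to_csv(path, sep="\t", index=False)
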