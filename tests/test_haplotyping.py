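"""Exact-match haplotype grouping, combination, naming and recombinant flags."""

import numpy as np
import pytest

from gluhap.haplotyping import (
    AMBIGUOUS,
    assign_names,
    combine_subunits,
    combined_names,
    detect_recombinants,
    flank_consistency,
    group_haplotypes,
)
from gluhap.phylo import CladePartition
from gluhap.variant_core import ALT, MISSING, REF

from .conftest import make_matrix


def _partition(calls, regions="coding-x", samples=None, scope=("coding-x",)):
    return group_haplotypes(make_matrix(calls, samples=samples, regions=regions), scope)


class TestGroupHaplotypes:
    def test_basic_grouping(self):
        # vectors (A, A, B) over one site -> two haplotypes of sizes 2 and 1
        p = _partition([[REF, REF, ALT]])
        assert p.n_haplotypes == 2
        assert sorted(p.member_counts().values(), reverse=True) == [2, 1]
        assert p.assignment["s0"] == p.assignment["s1"] != p.assignment["s2"]

    def test_missing_compatible_with_two_is_ambiguous(self):
        calls = np.array([[REF, ALT, MISSING], [REF, REF, REF]], dtype=np.int8)
        p = _partition(calls)
        assert p.assignment["s2"] == AMBIGUOUS
        assert p.n_haplotypes == 2

    def test_missing_compatible_with_one_is_adopted(self):
        calls = np.array([[REF, ALT, MISSING], [REF, ALT, ALT]], dtype=np.int8)
        p = _partition(calls)
        assert p.assignment["s2"] == p.assignment["s1"]

    def test_planted_pools_recovered(self, fixture_panel):
        """Zero-noise panel: grouping recovers exactly the planted haplotypes."""
        _, _, truth = fixture_panel
        import tempfile

        from gluhap.variant_core import apply_site_filters, call_genotypes, read_vcf_region

        vcf_text = fixture_panel[0]
        with tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False) as fh:
            fh.write(vcf_text)
            path = fh.name
        m = apply_site_filters(call_genotypes(read_vcf_region(path, truth.locus)))
        px = group_haplotypes(m, ("coding-x",))
        py = group_haplotypes(m, ("coding-y",))
        combined = combine_subunits(px, py)
        assert px.n_haplotypes == truth.n_x_haplotypes()
        assert py.n_haplotypes == truth.n_y_haplotypes()
        assert combined.n_haplotypes == truth.n_combined_haplotypes()
        # grouping matches the planted assignment exactly (same partitions)
        planted = truth.samples.set_index("sample")["x_haplotype"]
        for s1 in px.samples:
            for s2 in px.samples:
                same_called = px.assignment[s1] == px.assignment[s2]
                same_planted = planted[s1] == planted[s2]
                assert same_called == same_planted

    def test_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(4)
        calls = rng.choice([REF, ALT], size=(10, 12)).astype(np.int8)
        names = [f"s{i:02d}" for i in range(12)]
        p1 = _partition(calls, samples=names)
        perm = rng.permutation(12)
        p2 = _partition(calls[:, perm], samples=[names[i] for i in perm])
        for a in names:
            for b in names:
                assert (p1.assignment[a] == p1.assignment[b]) == (
                    p2.assignment[a] == p2.assignment[b]
                )
        # canonical ids identical, not merely isomorphic
        assert p1.assignment == p2.assignment

    def test_refinement_adding_sites_never_merges(self):
        rng = np.random.default_rng(5)
        regions = ["coding-x"] * 6 + ["flank-x"] * 4
        calls = rng.choice([REF, ALT], size=(10, 15)).astype(np.int8)
        m = make_matrix(calls, regions=regions)
        p_sub = group_haplotypes(m, ("coding-x",))
        p_full = group_haplotypes(m, ("coding-x", "flank-x"))
        assert p_full.n_haplotypes >= p_sub.n_haplotypes
        for a in p_sub.samples:
            for b in p_sub.samples:
                if p_full.assignment[a] == p_full.assignment[b]:
                    assert p_sub.assignment[a] == p_sub.assignment[b]

    def test_empty_scope_error(self):
        m = make_matrix([[REF, ALT]])
        with pytest.raises(ValueError):
            group_haplotypes(m, ())
        with pytest.raises(ValueError):
            group_haplotypes(m, ("coding-y",))  # no sites in scope


class TestCombineSubunits:
    def _two_region_matrix(self, x_rows, y_rows, samples=None):
        calls = np.array(x_rows + y_rows, dtype=np.int8)
        regions = ["coding-x"] * len(x_rows) + ["coding-y"] * len(y_rows)
        return make_matrix(calls, samples=samples, regions=regions)

    def test_perfect_linkage(self):
        # 5 x-haplotypes each paired with its own y-haplotype -> 5 combined
        x = np.eye(5, dtype=np.int8)[:, [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]]
        m = self._two_region_matrix(list(x), list(x))
        px = group_haplotypes(m, ("coding-x",))
        py = group_haplotypes(m, ("coding-y",))
        c = combine_subunits(px, py)
        assert px.n_haplotypes == py.n_haplotypes == c.n_haplotypes == 5

    def test_one_x_with_three_y(self):
        # single x haplotype against three y haplotypes -> 3 combined
        m = self._two_region_matrix(
            [[REF, REF, REF]], [[REF, ALT, REF], [REF, REF, ALT]]
        )
        px = group_haplotypes(m, ("coding-x",))
        py = group_haplotypes(m, ("coding-y",))
        c = combine_subunits(px, py)
        assert px.n_haplotypes == 1 and py.n_haplotypes == 3
        assert c.n_haplotypes == 3

    def test_disjoint_pairings(self):
        # 4 x-haps x 4 y-haps observed in 6 distinct pairings -> 6 combined
        x_class = [0, 0, 1, 1, 2, 3]
        y_class = [0, 1, 1, 2, 2, 3]
        xv = np.eye(4, dtype=np.int8)
        x_rows = xv[:, x_class]
        y_rows = xv[:, y_class]
        m = self._two_region_matrix(list(x_rows), list(y_rows))
        c = combine_subunits(
            group_haplotypes(m, ("coding-x",)), group_haplotypes(m, ("coding-y",))
        )
        assert c.n_haplotypes == 6

    def test_ambiguous_propagates(self):
        m = self._two_region_matrix([[REF, ALT, MISSING]], [[REF, ALT, REF], [ALT, REF, REF]])
        px = group_haplotypes(m, ("coding-x",))
        py = group_haplotypes(m, ("coding-y",))
        assert px.assignment["s2"] == AMBIGUOUS
        assert combine_subunits(px, py).assignment["s2"] == AMBIGUOUS

    def test_differing_universes_rejected(self):
        p1 = _partition([[REF, ALT]], samples=["a", "b"])
        p2 = _partition([[REF, ALT]], samples=["a", "c"], regions="coding-y", scope=("coding-y",))
        with pytest.raises(ValueError):
            combine_subunits(p1, p2)


class TestFlankConsistency:
    def test_identity_scope_zero(self):
        p = _partition([[REF, ALT, ALT]])
        assert flank_consistency(p, p) == 0

    def test_flanks_in_linkage_add_nothing(self, fixture_run):
        _, summary = fixture_run
        assert summary["n_added_by_flanks"] == 0

    def test_planted_flank_mutation_splits(self):
        regions = ["coding-x", "flank-x"]
        # two samples identical in coding, split by a flank-only variant
        calls = np.array([[REF, REF], [REF, ALT]], dtype=np.int8)
        m = make_matrix(calls, regions=regions)
        p_coding = group_haplotypes(m, ("coding-x",))
        p_full = group_haplotypes(m, ("coding-x", "flank-x"))
        assert flank_consistency(p_coding, p_full) == 1


class TestAssignNames:
    def _clades(self, p, sub=1, major="I"):
        haps = list(p.haplotypes)
        return CladePartition(haps, {h: major for h in haps}, {h: sub for h in haps})

    def test_letters_by_carrier_count(self):
        calls = np.array([[REF] * 10 + [ALT] * 3], dtype=np.int8)
        p = _partition(calls)
        names = assign_names(p, self._clades(p), "x")
        by_count = sorted(p.haplotypes, key=lambda h: -p.member_counts()[h])
        assert names[by_count[0]] == "Dx1a"  # 10 carriers
        assert names[by_count[1]] == "Dx1b"  # 3 carriers

    def test_singleton_subclade_gets_a(self):
        p = _partition([[REF, REF]])
        assert assign_names(p, self._clades(p, sub=7), "y").names.popitem()[1] == "Dy7a"

    def test_deterministic_under_shuffle(self):
        rng = np.random.default_rng(6)
        calls = rng.choice([REF, ALT], size=(4, 20)).astype(np.int8)
        names_runs = []
        order = np.arange(20)
        samples = [f"s{i:02d}" for i in range(20)]
        for _ in range(3):
            rng.shuffle(order)
            p = _partition(calls[:, order], samples=[samples[i] for i in order])
            names = assign_names(p, self._clades(p), "x")
            names_runs.append({s: names[p.assignment[s]] for s in samples})
        assert names_runs[0] == names_runs[1] == names_runs[2]

    def test_missing_clade_error(self):
        p = _partition([[REF, ALT]])
        empty = CladePartition([], {}, {})
        with pytest.raises(ValueError, match="lacks"):
            assign_names(p, empty, "x")

    def test_combined_names_format(self, fixture_run):
        import pandas as pd

        out, _ = fixture_run
        df = pd.read_csv(out / "haplotypes_combined.tsv", sep="\t")
        assert df["name"].str.match(r"^x\d+[a-z]\+y\d+[a-z]$").all()


class TestDetectRecombinants:
    def _setup(self, pairs, clade_x, clade_y):
        """Build a combined partition from explicit per-sample (x, y) pairs."""
        samples = [f"s{i:02d}" for i in range(len(pairs))]
        xs = sorted({p[0] for p in pairs})
        ys = sorted({p[1] for p in pairs})
        # one-hot encode haplotype classes as allele vectors
        x_rows = np.array([[1 if xs.index(p[0]) == k else 0 for p in pairs] for k in range(len(xs))])
        y_rows = np.array([[1 if ys.index(p[1]) == k else 0 for p in pairs] for k in range(len(ys))])
        calls = np.vstack([x_rows, y_rows]).astype(np.int8)
        regions = ["coding-x"] * len(xs) + ["coding-y"] * len(ys)
        m = make_matrix(calls, samples=samples, regions=regions)
        px = group_haplotypes(m, ("coding-x",))
        py = group_haplotypes(m, ("coding-y",))
        combined = combine_subunits(px, py)
        # map planted labels to the canonical haplotype ids
        x_of = {px.assignment[s]: pairs[i][0] for i, s in enumerate(samples)}
        y_of = {py.assignment[s]: pairs[i][1] for i, s in enumerate(samples)}
        xc = CladePartition(
            list(px.haplotypes),
            {h: clade_x[x_of[h]] for h in px.haplotypes},
            {h: 1 if clade_x[x_of[h]] == "I" else 2 for h in px.haplotypes},
        )
        yc = CladePartition(
            list(py.haplotypes),
            {h: clade_y[y_of[h]] for h in py.haplotypes},
            {h: 1 if clade_y[y_of[h]] == "I" else 2 for h in py.haplotypes},
        )
        return combined, xc, yc, samples

    def test_minority_discordant_pairing_flagged(self):
        pairs = [("x1", "y1")] * 10 + [("x1", "y9")]  # y9 from another clade
        combined, xc, yc, samples = self._setup(
            pairs, {"x1": "I"}, {"y1": "I", "y9": "III"}
        )
        calls = detect_recombinants(combined, xc, yc)
        assert [c.sample for c in calls] == [samples[-1]]
        assert calls[0].x_major == "I" and calls[0].y_major == "III"
        assert calls[0].expected_y_major == "I"

    def test_perfect_linkage_no_flags(self):
        pairs = [("x1", "y1")] * 5 + [("x2", "y2")] * 5
        combined, xc, yc, _ = self._setup(
            pairs, {"x1": "I", "x2": "II"}, {"y1": "I", "y2": "II"}
        )
        assert detect_recombinants(combined, xc, yc) == []

    def test_tied_pairings_flag_nothing(self):
        pairs = [("x1", "y1")] * 3 + [("x1", "y9")] * 3
        combined, xc, yc, _ = self._setup(pairs, {"x1": "I"}, {"y1": "I", "y9": "III"})
        assert detect_recombinants(combined, xc, yc) == []

    def test_planted_recombinants_exact(self, fixture_run):
        """Precision and recall are both 1.0 on the zero-noise panel."""
        import pandas as pd

        out, summary = fixture_run
        truth = pd.read_csv(out / "truth_samples.tsv", sep="\t")
        planted = sorted(truth.loc[truth["is_recombinant"], "sample"])
        assert summary["recombinants"] == planted
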