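import pytest

from duinet.og_filter import (
    OrthoGroup,
    check_subclass_monophyly,
    filter_orthogroups,
    trim_alignment,
)
from duinet.phylo import parse_newick

SUBS3 = {"A1": "S1", "A2": "S1", "B1": "S2", "B2": "S2", "C1": "S3", "C2": "S3"}


class TestTrimming:
    def test_gappy_column_dropped(self):
        og = OrthoGroup(
            "og1",
            {"a": "-AC", "b": "-AC", "c": "-AC", "d": "KAC"},
        )
        out, cols, seqs = trim_alignment(og)
        assert cols == [0]
        assert seqs == []
        assert out.n_columns == 2

    def test_half_missing_column_kept(self):
        # exactly 50% missing is not "more than 50%"
        og = OrthoGroup("og1", {"a": "-A", "b": "-A", "c": "KA", "d": "KA"})
        out, cols, _ = trim_alignment(og)
        assert cols == []

    def test_gappy_sequence_dropped_after_column_trim(self):
        n = 100
        seqs = {f"s{i}": "A" * n for i in range(4)}
        seqs["gappy"] = "-" * 85 + "A" * 15
        og = OrthoGroup("og1", seqs)
        out, cols, dropped = trim_alignment(og)
        assert dropped == ["gappy"]
        assert "gappy" not in out.sequences

    def test_gapless_identity(self):
        og = OrthoGroup("og1", {"a": "MKV", "b": "MKI", "c": "MRV"})
        out, cols, seqs = trim_alignment(og)
        assert out.sequences == og.sequences
        assert cols == [] and seqs == []

    def test_absent_species_count_as_missing(self):
        og = OrthoGroup("og1", {"a": "MK", "b": "MK"})
        out, cols, _ = trim_alignment(og, all_species=["a", "b", "c", "d", "e"])
        # 3 of 5 species absent -> 60% missing everywhere
        assert cols == [0, 1]
        assert out.is_empty()

    def test_idempotent(self):
        og = OrthoGroup(
            "og1",
            {"a": "-ACD", "b": "-ACD", "c": "-ACD", "d": "KACD", "e": "K-CD"},
        )
        once, _, _ = trim_alignment(og)
        twice, cols, seqs = trim_alignment(once)
        assert twice.sequences == once.sequences
        assert cols == [] and seqs == []


class TestMonophyly:
    def test_clean_subclasses_pass(self):
        t = parse_newick(
            "((A1:1,A2:1):1,((B1:1,B2:1):1,(C1:1,C2:1):1):1);",
            subclass=SUBS3,
        )
        assert check_subclass_monophyly(t).passed

    def test_single_intruder_identified(self):
        subs = dict(SUBS3, B3="S2")
        t = parse_newick(
            "((A1:1,(B3:1,A2:1):1):1,((B1:1,B2:1):1,(C1:1,C2:1):1):1);",
            subclass=subs,
        )
        res = check_subclass_monophyly(t)
        assert not res.passed
        assert res.offending_species == frozenset({"B3"})

    def test_interleaved_clades_have_no_small_fix(self):
        # alternate A/B tips along a caterpillar: no 1-2 tip removal helps
        subs = {f"A{i}": "S1" for i in range(1, 5)}
        subs.update({f"B{i}": "S2" for i in range(1, 5)})
        subs.update({"C1": "S3", "C2": "S3"})
        t = parse_newick(
            "(((((((((A1:1,B1:1):1,A2:1):1,B2:1):1,A3:1):1,B3:1):1,A4:1):1,"
            "B4:1):1,(C1:1,C2:1):1):1);",
            subclass=subs,
        )
        res = check_subclass_monophyly(t)
        assert not res.passed
        assert res.offending_species == frozenset()

    def test_two_subclasses_vacuous_pass(self):
        t = parse_newick(
            "((A1:1,B1:1):1,(A2:1,B2:1):1);",
            subclass={"A1": "S1", "A2": "S1", "B1": "S2", "B2": "S2"},
        )
        with pytest.warns(UserWarning, match="fewer than three"):
            assert check_subclass_monophyly(t).passed

    def test_simulated_gene_trees_pass(self, species_tree_30):
        # gene trees are restrictions of the species tree: monophyly holds
        from duinet import synthetic

        sims = synthetic.simulate_gene_trees(
            species_tree_30, 5, 0.0, 1.0, 0.2, 0.2, seed=4,
            min_species=10, min_foreground=2,
        )
        for _, gt, _ in sims:
            assert check_subclass_monophyly(gt).passed


class TestRetention:
    def _og(self, n_species, n_fg):
        seqs = {f"bg{i}": "MK" for i in range(n_species - n_fg)}
        seqs.update({f"fg{i}": "MK" for i in range(n_fg)})
        return OrthoGroup("og", seqs)

    @pytest.mark.parametrize(
        "n_species,n_fg,kept",
        [
            (15, 4, True),   # stated boundary: retained
            (14, 6, False),  # too few species
            (20, 3, False),  # too few foreground
            (15, 3, False),
            (36, 10, True),
        ],
    )
    def test_boundaries(self, n_species, n_fg, kept):
        og = self._og(n_species, n_fg)
        fg = {f"fg{i}" for i in range(10)}
        out = filter_orthogroups([og], foreground=fg)
        assert (len(out) == 1) is kept

    def test_idempotent_and_order_stable(self):
        ogs = [self._og(16, 5), self._og(14, 5), self._og(20, 4)]
        for og, name in zip(ogs, "abc"):
            og.og_id = name
        fg = {f"fg{i}" for i in range(10)}
        once = filter_orthogroups(ogs, foreground=fg)
        twice = filter_orthogroups(once, foreground=fg)
        assert [o.og_id for o in once] == ["a", "c"]
        assert twice == once
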