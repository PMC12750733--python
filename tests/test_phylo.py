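import numpy as np
import pytest

from duinet import phylo, synthetic
from duinet.phylo import NewickError, parse_newick, pic_contrasts, write_newick

from oracles import brownian_tips, gls_contrasts


class TestNewickIO:
    def test_parse_small_tree(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert sorted(t.tip_labels) == ["A", "B", "C"]
        assert t.root_to_tip() == {"A": 2.0, "B": 2.0, "C": 2.0}

    def test_roundtrip_preserves_structure(self):
        st = synthetic.make_species_tree(20, 2, [2, 2], seed=4)
        text = write_newick(st)
        again = parse_newick(text, foreground=st.foreground)
        assert sorted(again.tip_labels) == sorted(st.tip_labels)
        d1, d2 = st.root_to_tip(), again.root_to_tip()
        for sp in d1:
            assert d1[sp] == pytest.approx(d2[sp], rel=1e-9)
        # idempotence
        assert write_newick(again) == text

    def test_duplicate_labels_rejected(self):
        with pytest.raises(NewickError, match="A"):
            parse_newick("((A:1,A:1):1,B:1);")

    def test_malformed_newick_rejected(self):
        with pytest.raises(NewickError):
            parse_newick("((A:1,B:1:1,C;")


class TestRootToTip:
    def test_zero_lengths(self):
        t = parse_newick("((A:0,B:0):0,C:0);")
        assert all(v == 0.0 for v in t.root_to_tip().values())

    def test_matches_explicit_path_walk(self):
        st = synthetic.make_species_tree(50, 3, [2, 2, 2], seed=9)
        got = st.root_to_tip()
        # brute force: walk up from each leaf
        for leaf in st.tree.leaf_node_iter():
            total, cur = 0.0, leaf
            while cur.parent_node is not None:
                total += cur.edge.length or 0.0
                cur = cur.parent_node
            assert got[leaf.taxon.label] == pytest.approx(total, abs=1e-12)

    def test_prune_preserves_path_lengths(self, species_tree_30):
        keep = sorted(species_tree_30.tip_labels)[:12]
        pruned = species_tree_30.prune_to(keep)
        full = species_tree_30.root_to_tip()
        sub = pruned.root_to_tip()
        # pruning to a taxon subset can shift the root to the subset MRCA;
        # all retained tips shift by the same amount (ultrametric input)
        offsets = {s: full[s] - sub[s] for s in keep}
        assert max(offsets.values()) - min(offsets.values()) < 1e-9


class TestContrasts:
    def test_two_tip_closed_form(self):
        t = parse_newick("(A:1,B:1);")
        u = pic_contrasts(t, {"A": 1.0, "B": 3.0})
        assert u.shape == (1,)
        assert u[0] == pytest.approx((1 - 3) / np.sqrt(2))

    def test_constant_values_give_zero(self, species_tree_30):
        vals = {s: 7.7 for s in species_tree_30.tip_labels}
        assert np.allclose(pic_contrasts(species_tree_30, vals), 0.0)

    def test_linearity(self, species_tree_30, rng):
        tips = species_tree_30.tip_labels
        x = {s: rng.normal() for s in tips}
        y = {s: rng.normal() for s in tips}
        ux = pic_contrasts(species_tree_30, x)
        uy = pic_contrasts(species_tree_30, y)
        uxy = pic_contrasts(
            species_tree_30, {s: 2 * x[s] - 3 * y[s] for s in tips}
        )
        assert np.allclose(uxy, 2 * ux - 3 * uy, atol=1e-10)

    def test_matches_gls_whitening_on_random_tree(self, rng):
        tree = synthetic.make_species_tree(20, 2, [2, 2], seed=17)
        vals = {s: rng.normal() for s in tree.tip_labels}
        u = pic_contrasts(tree, vals)
        w = gls_contrasts(tree, vals)
        assert np.max(np.abs(np.sort(np.abs(u)) - np.sort(np.abs(w)))) < 1e-8

    def test_brownian_contrasts_are_standard_normal(self, species_tree_30):
        rng = np.random.default_rng(10)
        from scipy import stats

        us = np.concatenate(
            [
                pic_contrasts(
                    species_tree_30, brownian_tips(species_tree_30, rng)
                )
                for _ in range(300)
            ]
        )
        assert stats.kstest(us, "norm").pvalue > 0.01

    def test_zero_length_cherry_raises(self):
        t = parse_newick("((A:0,B:0):1,C:1);")
        # terminal zeros are nudged by the epsilon policy, so this works
        u = pic_contrasts(t, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert np.all(np.isfinite(u))

    def test_matches_r_ape_pic(self, tmp_path):
        """Cross-check against the ape reference implementation."""
        import subprocess

        tree = synthetic.make_species_tree(12, 1, [2], seed=3)
        rng = np.random.default_rng(2)
        vals = {s: float(rng.normal()) for s in tree.tip_labels}
        nwk = tree.to_newick()
        script = tmp_path / "pic.R"
        ordered = sorted(vals)
        script.write_text(
            f'library(ape)\ntr <- read.tree(text="{nwk.strip()}")\n'
            "x <- c(" + ",".join(f"{vals[s]}" for s in ordered) + ")\n"
            "names(x) <- c(" + ",".join(f'"{s}"' for s in ordered) + ")\n"
            "cat(sort(abs(pic(x, tr))), sep='\\n')\n"
        )
        res = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=120
        )
        assert res.returncode == 0, res.stderr
        ref = np.sort(np.array([float(v) for v in res.stdout.split()]))
        mine = np.sort(np.abs(pic_contrasts(tree, vals)))
        assert np.allclose(mine, ref, atol=1e-6)
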