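import numpy as np
import pytest

from duinet import synthetic
from duinet.convergence import _foreground_clades


class TestSpeciesTree:
    def test_study_scale_tree(self, species_tree_36):
        t = species_tree_36
        assert t.n_tips == 36
        assert len(t.foreground) == 10
        clades = _foreground_clades(t)
        assert len(clades) == 6
        assert sorted(len(c) for c in clades) == [1, 1, 2, 2, 2, 2]
        # three monophyletic subclasses
        from duinet.og_filter import check_subclass_monophyly

        assert check_subclass_monophyly(t).passed

    def test_minimal_tree(self):
        t = synthetic.make_species_tree(4, 1, [1], seed=7)
        assert t.n_tips == 4
        assert len(t.foreground) == 1

    def test_seed_determinism(self):
        a = synthetic.make_species_tree(36, 6, [2, 2, 2, 2, 1, 1], seed=1)
        b = synthetic.make_species_tree(36, 6, [2, 2, 2, 2, 1, 1], seed=1)
        assert a.to_newick() == b.to_newick()

    def test_impossible_placement_rejected(self):
        with pytest.raises(ValueError, match="clade"):
            synthetic.make_species_tree(10, 4, [2, 2, 2, 2], seed=0)

    def test_ultrametric(self, species_tree_36):
        d = list(species_tree_36.root_to_tip().values())
        assert max(d) - min(d) < 1e-9


class TestGeneTrees:
    def test_class_fractions(self, species_tree_30):
        sims = synthetic.simulate_gene_trees(
            species_tree_30, 100, 0.2, 0.3, 0.2, 0.1, seed=3
        )
        assert len(sims) == 100
        classes = [t.convergence_class for _, _, t in sims]
        assert classes.count("constrained") == 20
        ids = [g for g, _, _ in sims]
        assert len(set(ids)) == 100

    def test_degenerate_limit_is_scalar_multiple(self, species_tree_30):
        sims = synthetic.simulate_gene_trees(
            species_tree_30, 5, 0.0, 1.0, 0.0, 0.0, seed=5, gene_rate_sd=0.3
        )
        ref = species_tree_30.root_to_tip()
        for _, gt, _ in sims:
            d = gt.root_to_tip()
            ratios = {s: d[s] / ref[s] for s in ref}
            vals = list(ratios.values())
            assert max(vals) - min(vals) < 1e-9

    def test_constrained_foreground_runs_slower(self, species_tree_30):
        sims = synthetic.simulate_gene_trees(
            species_tree_30, 200, 1.0, 0.3, 0.2, 0.0, seed=6
        )
        fg = species_tree_30.foreground
        ratios = []
        for _, gt, _ in sims:
            d = gt.root_to_tip()
            mf = np.mean([d[s] for s in d if s in fg])
            mb = np.mean([d[s] for s in d if s not in fg])
            ratios.append(mf / mb)
        assert np.mean(ratios) < 1.0

    def test_bad_multiplier_rejected(self, species_tree_30):
        with pytest.raises(ValueError):
            synthetic.simulate_gene_trees(
                species_tree_30, 5, 0.2, 0.0, 0.2, 0.0, seed=1
            )

    def test_filter_safe_respects_retention_rule(self, species_tree_36):
        sims = synthetic.simulate_gene_trees(
            species_tree_36, 50, 0.0, 1.0, 0.1, 0.3, seed=2, filter_safe=True
        )
        for _, gt, _ in sims:
            assert gt.n_tips >= 15
            assert len(set(gt.tip_labels) & species_tree_36.foreground) >= 4


class TestCodonAlignment:
    def test_zero_branch_star_copies_root(self):
        from duinet.phylo import parse_newick

        star = parse_newick("(A:0,B:0,C:0);")
        seqs = synthetic.simulate_codon_alignment(star, 50, 0.5, 0.5, 2.0, seed=3)
        assert seqs["A"] == seqs["B"] == seqs["C"]
        assert len(seqs["A"]) == 150

    def test_determinism_and_no_stops(self, mixed_10taxon_tree):
        a = synthetic.simulate_codon_alignment(
            mixed_10taxon_tree, 40, 0.5, 0.1, 2.0, seed=9
        )
        b = synthetic.simulate_codon_alignment(
            mixed_10taxon_tree, 40, 0.5, 0.1, 2.0, seed=9
        )
        assert a == b
        from duinet.codon_model import encode_alignment

        enc = encode_alignment(a)  # raises on in-frame stops
        assert all(len(v) == 40 for v in enc.values())

    def test_missing_branch_length_rejected(self):
        from duinet.phylo import parse_newick

        t = parse_newick("((A:1,B),C:1);")
        with pytest.raises(ValueError):
            synthetic.simulate_codon_alignment(t, 10, 0.5, 0.5, 2.0, seed=1)


class TestCounts:
    def test_shape_and_truth(self):
        cm, truth = synthetic.simulate_counts(500, 8, de_frac=0.02, seed=1)
        assert cm.counts.shape == (500, 8)
        assert truth["is_de"].sum() == 10
        assert cm.sex_ratios.between(0, 1).all()

    def test_null_construction_uncorrelated(self):
        from duinet import expression

        cm, _ = synthetic.simulate_counts(800, 8, de_frac=0.0, seed=2)
        norm = expression.cpm(cm.counts)
        sig = cm.sex_ratios.to_numpy()
        from scipy import stats

        ps = [
            stats.spearmanr(norm.iloc[i], sig).pvalue
            for i in range(0, 800, 8)
        ]
        assert np.mean(np.array(ps) < 0.05) < 0.15

    def test_planted_log_ratio_magnitude(self):
        cm, truth = synthetic.simulate_counts(
            5000, 8, de_frac=0.1, lfc_mean=2.0, dispersion=0.05, seed=3,
            male_up_frac=0.0,
        )
        x = cm.sex_ratios.to_numpy()
        dx = x[:4].mean() - x[4:].mean()
        planted = truth.index[truth["is_de"]]
        obs = []
        for f in planted[:500]:
            a = cm.counts.loc[f].iloc[:4].mean() + 0.5
            b = cm.counts.loc[f].iloc[4:].mean() + 0.5
            obs.append(abs(np.log2(a / b)))
        assert abs(np.median(obs) - 2.0 * abs(dx)) < 0.5

    def test_bad_dispersion_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_counts(10, 8, dispersion=0.0, seed=1)


class TestInteractome:
    def test_forced_cross_edges(self):
        nodes_a = [f"n{i + 1:04d}" for i in range(5)]
        nodes_b = [f"n{i + 6:04d}" for i in range(5)]
        g, truth = synthetic.simulate_interactome(
            40, 0.0, nodes_a, nodes_b, 1.0, seed=4
        )
        cross = [
            (a, b) for a in nodes_a for b in nodes_b if g.has_edge(a, b)
        ]
        assert len(cross) == 25
        assert all(d["score"] >= 0.400 for _, _, d in g.edges(data=True))

    def test_determinism(self):
        a, _ = synthetic.simulate_interactome(30, 0.1, [], [], 0.1, seed=5)
        b, _ = synthetic.simulate_interactome(30, 0.1, [], [], 0.1, seed=5)
        assert sorted(a.edges) == sorted(b.edges)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_interactome(10, 0.5, [], [], 0.2, seed=1)
        with pytest.raises(ValueError):
            synthetic.simulate_interactome(10, 1.5, [], [], 1.6, seed=1)


class TestHitTable:
    def test_all_pass_filters_when_drawn_passing(self):
        from duinet.lncrna_hits import filter_hits

        genes = synthetic.make_gene_intervals(50, 10, seed=1)
        hits, _ = synthetic.simulate_hit_table(genes, 10, 10, 1.0, seed=2)
        assert len(filter_hits(hits)) == len(hits)

    def test_unbiased_placement_proportional(self):
        genes = synthetic.make_gene_intervals(100, 20, seed=3)
        hits, _ = synthetic.simulate_hit_table(genes, 40, 50, 1.0, seed=4)
        lengths = genes.set_index("gene_id").eval("end - start")
        focal = set(genes.loc[genes["focal"], "gene_id"])
        p_focal = lengths[list(focal)].sum() / lengths.sum()
        # count hits landing in focal genes
        focal_iv = genes[genes["focal"]]
        n_focal = 0
        for _, h in hits.iterrows():
            m = focal_iv[
                (focal_iv["seqid"] == h["seqid"])
                & (focal_iv["start"] <= h["start"])
                & (h["end"] <= focal_iv["end"])
            ]
            n_focal += len(m) > 0
        n = len(hits)
        se = np.sqrt(p_focal * (1 - p_focal) * n)
        assert abs(n_focal - p_focal * n) < 4 * se

    def test_empty_intervals_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            synthetic.simulate_hit_table(pd.DataFrame(), 5, 5, 1.0, seed=1)
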