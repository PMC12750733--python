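"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and
returns machine-readable truth labels so downstream recovery can be
scored.  The generators emulate, at desk scale, the statistical structure
of the motivating study's inputs: a 36-taxon bivalve species tree with six
independent foreground (DUI) clades nested in three monophyletic
subclasses; per-orthogroup gene trees whose foreground branches run slower
(constrained) or faster (accelerated) than the reference; codon alignments
under branch-specific dN/dS; a mitochondrial tree sharing branch-rate
deviations with a subset of genes (rate covariation); an 8-sample
negative-binomial count matrix with a 4-vs-4 sex-bias design; lncRNA hit
tables with over-representation planted in a focal gene set; and a scored
interactome with a planted dense cross-set module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from . import codon_model
from .expression import CountMatrix, MALE, FEMALE
from .phylo import TaggedTree

__all__ = [
    "SimTruth",
    "make_species_tree",
    "simulate_gene_trees",
    "simulate_codon_alignment",
    "simulate_rate_covarying_trees",
    "simulate_counts",
    "simulate_interactome",
    "simulate_hit_table",
    "make_gene_intervals",
]

SUBCLASSES = ("Pteriomorphia", "Palaeoheterodonta", "Heterodonta")


@dataclass
class SimTruth:
    """Planted ground truth for one simulated object."""

    gene_id: str
    convergence_class: str = "null"  # constrained | accelerated | null
    is_erc_linked: bool = False
    is_de: bool = False
    de_lfc: float = 0.0
    planted_module_member: bool = False


def _truth_frame(truths: Sequence[SimTruth]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in truths]).set_index("gene_id")


# -- species tree -----------------------------------------------------------


class _Unit:
    """Subtree under construction: root node, height of root, purity flag."""

    __slots__ = ("node", "height", "pure_fg")

    def __init__(self, node, height, pure_fg):
        self.node = node
        self.height = height
        self.pure_fg = pure_fg


def _merge(a: _Unit, b: _Unit, rng, scale: float = 1.0) -> _Unit:
    h = max(a.height, b.height) + float(rng.exponential(scale))
    parent = dendropy.Node()
    parent.add_child(a.node)
    parent.add_child(b.node)
    a.node.edge.length = h - a.height
    b.node.edge.length = h - b.height
    return _Unit(parent, h, a.pure_fg and b.pure_fg)


def _merge_all(units: list, rng, forbid_pure_pairs: bool) -> _Unit:
    """Random sequential ultrametric merging; optionally never merges two
    all-foreground units while a mixed pair is available (keeps planted
    foreground clades separated).

    Merge-height increments are proportional to the number of open
    lineages, which yields the long terminal branches characteristic of
    sparse taxon sampling across a deep clade.
    """
    units = list(units)
    n0 = len(units)
    while len(units) > 1:
        for _ in range(100):
            i, j = sorted(rng.choice(len(units), size=2, replace=False))
            if not forbid_pure_pairs:
                break
            if not (units[i].pure_fg and units[j].pure_fg):
                break
            if all(u.pure_fg for u in units):
                break
        scale = len(units) / n0
        b = units.pop(j)
        a = units.pop(i)
        units.append(_merge(a, b, rng, scale=scale))
    return units[0]


def make_species_tree(
    n_species: int,
    n_foreground_clades: int,
    clade_sizes: Sequence[int],
    seed: int,
) -> TaggedTree:
    """Random rooted binary ultrametric species tree with planted
    foreground clades.

    The requested foreground clades are monophyletic and mutually
    separated by background tips, and the tips partition into the three
    bivalve subclasses, each monophyletic.  The shape mimics a birth-death
    tree (random ultrametric merges); branch lengths are rescaled to mean
    0.1 substitutions/site.
    """
    clade_sizes = list(clade_sizes)
    if n_foreground_clades < 1 or len(clade_sizes) != n_foreground_clades:
        raise ValueError("clade_sizes must list one size per foreground clade")
    if any(s < 1 for s in clade_sizes):
        raise ValueError("clade sizes must be >= 1")
    n_fg = sum(clade_sizes)
    n_bg = n_species - n_fg
    if n_bg < n_foreground_clades or n_bg < 3:
        raise ValueError(
            "impossible clade placement: need at least one background tip "
            "per foreground clade and per subclass"
        )
    rng = np.random.default_rng(seed)

    labels = [f"sp{i + 1:03d}" for i in range(n_species)]
    fg_labels: list[list[str]] = []
    k = 0
    for size in clade_sizes:
        fg_labels.append(labels[k : k + size])
        k += size
    bg_labels = labels[k:]

    # distribute clades round-robin and background tips evenly over the
    # three subclasses, keeping at least one background tip per subclass
    clade_of_sub = {i: [] for i in range(3)}
    for ci in range(n_foreground_clades):
        clade_of_sub[ci % 3].append(ci)
    bg_of_sub = {i: [] for i in range(3)}
    for bi, lab in enumerate(bg_labels):
        bg_of_sub[bi % 3].append(lab)
    for i in range(3):
        if not bg_of_sub[i]:
            raise ValueError("impossible clade placement: empty subclass")

    ns = dendropy.TaxonNamespace()

    def leaf_unit(lab: str, pure: bool) -> _Unit:
        return _Unit(
            dendropy.Node(taxon=ns.require_taxon(label=lab)), 0.0, pure
        )

    sub_units = []
    subclass_map: dict[str, str] = {}
    for si in range(3):
        units = []
        for lab in bg_of_sub[si]:
            units.append(leaf_unit(lab, pure=False))
            subclass_map[lab] = SUBCLASSES[si]
        for ci in clade_of_sub[si]:
            clade = _merge_all(
                [leaf_unit(lab, pure=True) for lab in fg_labels[ci]],
                rng,
                forbid_pure_pairs=False,
            )
            for lab in fg_labels[ci]:
                subclass_map[lab] = SUBCLASSES[si]
            units.append(clade)
        sub_units.append(_merge_all(units, rng, forbid_pure_pairs=True))

    inner = _merge(sub_units[0], sub_units[1], rng)
    top = _merge(inner, sub_units[2], rng)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = top.node
    tree.is_rooted = True

    # rescale branch lengths to mean 0.1 substitutions/site
    lens = [e.length for e in tree.preorder_edge_iter() if e.length]
    scale = 0.1 / float(np.mean(lens))
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = e.length * scale

    fg_all = {lab for clade in fg_labels for lab in clade}
    return TaggedTree(tree, foreground=fg_all, subclass=subclass_map)


# -- gene trees -------------------------------------------------------------


def _scaled_gene_tree(
    species_tree: TaggedTree,
    keep: set[str],
    gene_rate: float,
    noise_sd: float,
    multiplier: float,
    rng,
) -> TaggedTree:
    gt = species_tree.prune_to(keep) if keep != set(species_tree.tip_labels) \
        else species_tree.clone()
    fg_nodes = set(gt.foreground_edges())
    for node in gt.tree.preorder_node_iter():
        if node is gt.tree.seed_node or node.edge.length is None:
            continue
        eps = float(rng.lognormal(0.0, noise_sd)) if noise_sd > 0 else 1.0
        m = multiplier if node in fg_nodes else 1.0
        node.edge.length = node.edge.length * gene_rate * eps * m
    return gt


def simulate_gene_trees(
    species_tree: TaggedTree,
    n_genes: int,
    constrained_frac: float,
    rate_multiplier: float,
    lognormal_noise_sd: float,
    missing_frac: float,
    seed: int,
    accelerated_frac: float = 0.0,
    gene_rate_sd: float = 0.3,
    filter_safe: bool = True,
    min_species: int = 15,
    min_foreground: int = 4,
) -> list[tuple[str, TaggedTree, SimTruth]]:
    """Gene trees on the species topology with planted rate convergence.

    Branch lengths are ``b * g_gene * eps_e * m`` with multiplicative
    lognormal edge noise and ``m = rate_multiplier`` on foreground branches
    of constrained genes (``1 / rate_multiplier`` for accelerated genes).
    A ``missing_frac`` of tips is dropped per gene; with ``filter_safe``
    the taxon draw is repeated until the gene would survive the
    orthogroup retention rule (>= min_species species, >= min_foreground
    foreground species).
    """
    if not 0 <= constrained_frac <= 1 or not 0 <= accelerated_frac <= 1:
        raise ValueError("class fractions must be in [0, 1]")
    if constrained_frac + accelerated_frac > 1:
        raise ValueError("class fractions sum above 1")
    if rate_multiplier <= 0:
        raise ValueError("rate_multiplier must be > 0")
    rng = np.random.default_rng(seed)
    tips = species_tree.tip_labels
    fg = species_tree.foreground

    n_con = round(n_genes * constrained_frac)
    n_acc = round(n_genes * accelerated_frac)
    classes = (
        ["constrained"] * n_con
        + ["accelerated"] * n_acc
        + ["null"] * (n_genes - n_con - n_acc)
    )

    out = []
    for gi, cls in enumerate(classes):
        gene_id = f"OG{gi + 1:05d}"
        keep = set(tips)
        if missing_frac > 0:
            for _ in range(200):
                mask = rng.random(len(tips)) >= missing_frac
                keep = {t for t, m in zip(tips, mask) if m}
                if not filter_safe:
                    if len(keep) >= 3:
                        break
                elif (
                    len(keep) >= min_species
                    and len(keep & fg) >= min_foreground
                ):
                    break
            else:
                keep = set(tips)
        gene_rate = float(rng.lognormal(0.0, gene_rate_sd)) if gene_rate_sd else 1.0
        mult = {
            "constrained": rate_multiplier,
            "accelerated": 1.0 / rate_multiplier,
            "null": 1.0,
        }[cls]
        gt = _scaled_gene_tree(
            species_tree, keep, gene_rate, lognormal_noise_sd, mult, rng
        )
        out.append((gene_id, gt, SimTruth(gene_id, convergence_class=cls)))
    return out


def simulate_rate_covarying_trees(
    species_tree: TaggedTree,
    n_genes: int,
    linked_frac: float,
    coupling: float = 1.0,
    shared_sd: float = 0.6,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[TaggedTree, list[tuple[str, TaggedTree, SimTruth]]]:
    """A mitochondrial tree plus gene trees, a fraction of which share its
    branch-rate deviations (the rate-covariation alternative hypothesis).

    Every edge of the species tree receives a lognormal rate deviation
    ``eta_e``; the mito tree uses it directly, linked genes use
    ``coupling * eta_e`` plus independent noise, unlinked genes get fresh
    independent deviations of matched variance.
    """
    rng = np.random.default_rng(seed)
    edges = [
        nd
        for nd in species_tree.tree.preorder_node_iter()
        if nd is not species_tree.tree.seed_node and nd.edge.length is not None
    ]
    eta = rng.normal(0.0, shared_sd, size=len(edges))

    def build(deviation: np.ndarray) -> TaggedTree:
        t = species_tree.clone()
        t_edges = [
            nd
            for nd in t.tree.preorder_node_iter()
            if nd is not t.tree.seed_node and nd.edge.length is not None
        ]
        for nd, dv in zip(t_edges, deviation):
            nd.edge.length = nd.edge.length * float(np.exp(dv))
        return t

    mito = build(eta + rng.normal(0.0, noise_sd, size=len(edges)))

    n_linked = round(n_genes * linked_frac)
    out = []
    for gi in range(n_genes):
        gene_id = f"OG{gi + 1:05d}"
        linked = gi < n_linked
        if linked:
            dev = coupling * eta + rng.normal(0.0, noise_sd, size=len(edges))
        else:
            total_sd = np.sqrt((coupling * shared_sd) ** 2 + noise_sd**2)
            dev = rng.normal(0.0, total_sd, size=len(edges))
        out.append(
            (gene_id, build(dev), SimTruth(gene_id, is_erc_linked=linked))
        )
    return mito, out


def simulate_joint_gene_trees(
    species_tree: TaggedTree,
    n_genes: int,
    constrained_frac: float,
    accelerated_frac: float,
    rate_multiplier: float,
    lognormal_noise_sd: float,
    missing_frac: float,
    erc_linked_frac: float,
    coupling: float = 1.0,
    shared_sd: float = 0.35,
    gene_rate_sd: float = 0.3,
    seed: int = 0,
    min_species: int = 15,
    min_foreground: int = 4,
) -> tuple[TaggedTree, list[tuple[str, TaggedTree, SimTruth]]]:
    """Gene trees with planted convergence AND rate covariation, plus the
    matching mitochondrial tree.

    Combines :func:`simulate_gene_trees` and
    :func:`simulate_rate_covarying_trees`: a shared lognormal branch-rate
    field ties the mito tree to ERC-linked genes (drawn preferentially
    from the constrained class, mirroring the enrichment of mito-nuclear
    coevolution among convergently evolving genes), while foreground
    branches of constrained/accelerated genes get the rate multiplier.
    """
    if rate_multiplier <= 0:
        raise ValueError("rate_multiplier must be > 0")
    rng = np.random.default_rng(seed)
    tips = species_tree.tip_labels
    fg = species_tree.foreground
    full_edges = [
        nd
        for nd in species_tree.tree.preorder_node_iter()
        if nd is not species_tree.tree.seed_node and nd.edge.length is not None
    ]
    eta = rng.normal(0.0, shared_sd, size=len(full_edges))

    def deviated_tree(dev: np.ndarray) -> TaggedTree:
        t = species_tree.clone()
        t_edges = [
            nd
            for nd in t.tree.preorder_node_iter()
            if nd is not t.tree.seed_node and nd.edge.length is not None
        ]
        for nd, dv in zip(t_edges, dev):
            nd.edge.length = nd.edge.length * float(np.exp(dv))
        return t

    mito = deviated_tree(eta + rng.normal(0.0, 0.1, size=len(full_edges)))

    n_con = round(n_genes * constrained_frac)
    n_acc = round(n_genes * accelerated_frac)
    classes = (
        ["constrained"] * n_con
        + ["accelerated"] * n_acc
        + ["null"] * (n_genes - n_con - n_acc)
    )
    # ERC-linked genes drawn mostly from the constrained class
    n_linked = round(n_genes * erc_linked_frac)
    linked_ids = set()
    order = list(range(n_con)) + list(range(n_con, n_genes))
    for gi in order[:n_linked]:
        linked_ids.add(gi)

    indep_sd = np.sqrt((coupling * shared_sd) ** 2)
    out = []
    for gi, cls in enumerate(classes):
        gene_id = f"OG{gi + 1:05d}"
        linked = gi in linked_ids
        if linked:
            dev = coupling * eta + rng.normal(0.0, 0.1, size=len(full_edges))
        else:
            dev = rng.normal(0.0, indep_sd, size=len(full_edges))
        base = deviated_tree(dev)

        keep = set(tips)
        if missing_frac > 0:
            for _ in range(200):
                mask = rng.random(len(tips)) >= missing_frac
                cand = {t for t, m in zip(tips, mask) if m}
                if len(cand) >= min_species and len(cand & fg) >= min_foreground:
                    keep = cand
                    break
        gene_rate = (
            float(rng.lognormal(0.0, gene_rate_sd)) if gene_rate_sd else 1.0
        )
        mult = {
            "constrained": rate_multiplier,
            "accelerated": 1.0 / rate_multiplier,
            "null": 1.0,
        }[cls]
        gt = _scaled_gene_tree(
            base, keep, gene_rate, lognormal_noise_sd, mult, rng
        )
        out.append(
            (
                gene_id,
                gt,
                SimTruth(gene_id, convergence_class=cls, is_erc_linked=linked),
            )
        )
    return mito, out


# -- codon alignments -------------------------------------------------------


def simulate_codon_alignment(
    tree: TaggedTree,
    n_codons: int,
    omega_bg: float,
    omega_fg: float,
    kappa: float,
    freqs: np.ndarray | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Site-independent GY94 simulation along the tree.

    Foreground branches (terminal edges of foreground tips plus all-
    foreground internal edges) evolve under ``omega_fg``, the rest under
    ``omega_bg``; the root sequence is drawn from ``freqs``.
    """
    for nd in tree.tree.preorder_node_iter():
        if nd is not tree.tree.seed_node and nd.edge.length is None:
            raise ValueError("tree must have branch lengths on every edge")
    if freqs is None:
        freqs = codon_model.uniform_frequencies()
    freqs = np.asarray(freqs, dtype=float)
    params = codon_model.ModelParams(
        kappa=kappa,
        omega={"background": omega_bg, "foreground": omega_fg},
        freqs=freqs,
    )
    rng = np.random.default_rng(seed)
    fg_nodes = set(tree.foreground_edges())

    q_by_class = {
        cls: codon_model.gy94_rate_matrix(params, cls)
        for cls in ("background", "foreground")
    }

    states = {tree.tree.seed_node: rng.choice(len(freqs), size=n_codons, p=freqs)}
    seqs: dict[str, str] = {}
    for node in tree.tree.preorder_node_iter():
        if node is not tree.tree.seed_node:
            cls = "foreground" if node in fg_nodes else "background"
            t = node.edge.length or 0.0
            P = codon_model.transition_matrices(
                q_by_class[cls], freqs, np.array([t])
            )[0]
            P = P / P.sum(axis=1, keepdims=True)
            cum = np.cumsum(P, axis=1)
            parent_states = states[node.parent_node]
            u = rng.random(n_codons)
            child = np.empty(n_codons, dtype=np.int64)
            for i, (ps, ui) in enumerate(zip(parent_states, u)):
                child[i] = np.searchsorted(cum[ps], ui, side="right")
            child = np.minimum(child, len(freqs) - 1)
            states[node] = child
        if node.is_leaf():
            seqs[node.taxon.label] = "".join(
                codon_model.SENSE_CODONS[i] for i in states[node]
            )
    return seqs


# -- count matrix -----------------------------------------------------------

DEFAULT_SEX_RATIOS = (0.95, 0.88, 0.81, 0.74, 0.26, 0.19, 0.12, 0.05)


def simulate_counts(
    n_features: int,
    n_samples: int,
    group_labels: Sequence[str] | None = None,
    sex_ratios: Sequence[float] | None = None,
    de_frac: float = 0.016,
    lfc_mean: float = 3.0,
    lfc_sd: float = 0.0,
    dispersion: float = 0.1,
    lib_size_range: tuple[int, int] = (8_000_000, 12_000_000),
    male_up_frac: float = 0.054,
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts with sex-ratio-coupled planted effects.

    Counts have mean ``mu_fs = L_s * q_f * 2^(lfc_f * x_s)`` where ``x_s``
    is the centered per-sample offspring sex ratio and ``lfc_f`` is zero
    for non-planted features.  The default design mirrors the study:
    8 samples, 4 male- vs 4 female-biased, with roughly 1.6% of features
    planted and most planted features higher in female-biased eggs.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if sex_ratios is None:
        sex_ratios = DEFAULT_SEX_RATIOS[:n_samples]
    sex_ratios = np.asarray(sex_ratios, dtype=float)
    if ((sex_ratios < 0) | (sex_ratios > 1)).any():
        raise ValueError("sex ratios must be in [0, 1]")
    if group_labels is None:
        group_labels = [MALE if s >= 0.5 else FEMALE for s in sex_ratios]
    if len(group_labels) != n_samples or len(sex_ratios) != n_samples:
        raise ValueError("group_labels and sex_ratios must match n_samples")

    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    features = [f"feat{i + 1:06d}" for i in range(n_features)]

    rel = rng.lognormal(0.0, 1.5, size=n_features)
    q = rel / rel.sum()
    L = rng.integers(lib_size_range[0], lib_size_range[1] + 1, size=n_samples)

    n_de = round(n_features * de_frac)
    lfc = np.zeros(n_features)
    if n_de:
        mag = (
            np.full(n_de, lfc_mean)
            if lfc_sd == 0
            else rng.normal(lfc_mean, lfc_sd, size=n_de)
        )
        sign = np.where(rng.random(n_de) < male_up_frac, 1.0, -1.0)
        lfc[:n_de] = mag * sign

    x = sex_ratios - sex_ratios.mean()
    mu = L[None, :] * q[:, None] * 2.0 ** (lfc[:, None] * x[None, :])
    size = 1.0 / dispersion
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=features, columns=samples),
        sex_ratios=pd.Series(sex_ratios, index=samples),
        groups=pd.Series(list(group_labels), index=samples),
    )
    truth = _truth_frame(
        [
            SimTruth(f, is_de=bool(l != 0), de_lfc=float(l))
            for f, l in zip(features, lfc)
        ]
    )
    return cm, truth


# -- interactome ------------------------------------------------------------


def simulate_interactome(
    n_nodes: int,
    background_edge_prob: float,
    set_A: Sequence[str],
    set_B: Sequence[str],
    planted_edge_prob: float,
    seed: int = 0,
    min_score: float = 0.400,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Erdos-Renyi interactome with a planted dense A-B cross module.

    All edges carry a confidence score drawn uniformly in
    ``[min_score, 1]`` so the whole graph survives the load-time score
    filter.
    """
    for prob in (background_edge_prob, planted_edge_prob):
        if not 0 <= prob <= 1:
            raise ValueError("edge probabilities must be in [0, 1]")
    if planted_edge_prob < background_edge_prob:
        raise ValueError("planted_edge_prob must be >= background_edge_prob")
    rng = np.random.default_rng(seed)
    nodes = [f"n{i + 1:04d}" for i in range(n_nodes)]
    known = set(set_A) | set(set_B)
    unknown = known - set(nodes)
    if unknown:
        raise ValueError(f"set members outside node universe: {sorted(unknown)}")
    a_set, b_set = set(set_A), set(set_B)

    g = nx.Graph()
    g.add_nodes_from(nodes)
    planted_pairs = {
        frozenset((a, b)) for a in a_set for b in b_set if a != b
    }
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            pair = frozenset((nodes[i], nodes[j]))
            prob = (
                planted_edge_prob
                if pair in planted_pairs
                else background_edge_prob
            )
            if rng.random() < prob:
                g.add_edge(
                    nodes[i],
                    nodes[j],
                    score=float(rng.uniform(min_score, 1.0)),
                )
    truth = _truth_frame(
        [
            SimTruth(n, planted_module_member=(n in known))
            for n in nodes
        ]
    )
    return g, truth


# -- lncRNA hit tables ------------------------------------------------------


def make_gene_intervals(
    n_genes: int,
    n_focal: int,
    seed: int = 0,
    n_seqs: int = 5,
    gene_length_range: tuple[int, int] = (2_000, 20_000),
    gap_range: tuple[int, int] = (500, 5_000),
) -> pd.DataFrame:
    """Non-overlapping strand-aware gene intervals on a few sequences."""
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    rows = []
    pos = dict.fromkeys(range(n_seqs), 0)
    for gi in range(n_genes):
        seq = int(gi % n_seqs)
        start = pos[seq] + int(rng.integers(*gap_range))
        length = int(rng.integers(*gene_length_range))
        rows.append(
            {
                "seqid": f"chr{seq + 1}",
                "start": start,
                "end": start + length,
                "strand": "+" if rng.random() < 0.5 else "-",
                "gene_id": f"gene{gi + 1:05d}",
                "focal": gi < n_focal,
            }
        )
        pos[seq] = start + length
    return pd.DataFrame(rows)


def simulate_hit_table(
    gene_intervals: pd.DataFrame,
    n_lncrnas: int,
    hits_per_lncrna: int,
    focal_gene_bias: float,
    seed: int = 0,
    pass_frac: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Similarity hits placed inside genes, focal genes over-weighted.

    Hit placement probability is proportional to gene length times
    ``focal_gene_bias`` for focal genes.  A ``1 - pass_frac`` fraction of
    hits is drawn to fail the identity/length/coverage filters.
    """
    if len(gene_intervals) == 0:
        raise ValueError("empty gene interval set")
    if focal_gene_bias < 1:
        raise ValueError("focal_gene_bias must be >= 1")
    rng = np.random.default_rng(seed)
    genes = gene_intervals.reset_index(drop=True)
    lengths = (genes["end"] - genes["start"]).to_numpy(dtype=float)
    w = lengths * np.where(genes["focal"].to_numpy(), focal_gene_bias, 1.0)
    w = w / w.sum()

    rows = []
    for li in range(n_lncrnas):
        qid = f"lnc{li + 1:04d}"
        qlen = int(rng.integers(300, 1_500))
        for _ in range(hits_per_lncrna):
            gi = int(rng.choice(len(genes), p=w))
            g = genes.iloc[gi]
            passing = rng.random() < pass_frac
            if passing:
                ident = float(rng.uniform(92.0, 100.0))
                cov = float(rng.uniform(0.55, 0.95))
                alen = max(110, int(cov * qlen))
            else:
                # violate exactly one of the three filters
                fail = rng.integers(3)
                ident = float(rng.uniform(92, 100)) if fail != 0 else float(
                    rng.uniform(60, 89)
                )
                cov = float(rng.uniform(0.55, 0.95)) if fail != 1 else float(
                    rng.uniform(0.1, 0.45)
                )
                alen = (
                    max(110, int(cov * qlen))
                    if fail != 2
                    else int(rng.integers(30, 95))
                )
            span = int(g["end"] - g["start"])
            alen = min(alen, max(span - 2, 10))
            start = int(g["start"]) + int(
                rng.integers(0, max(span - alen, 1))
            )
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(
                {
                    "query_id": qid,
                    "query_length": qlen,
                    "seqid": g["seqid"],
                    "start": start,
                    "end": start + alen,
                    "strand": strand,
                    "identity": ident,
                    "length": alen,
                    "coverage": cov,
                }
            )
    hits = pd.DataFrame(rows)
    truth = _truth_frame(
        [
            SimTruth(f"lnc{i + 1:04d}", is_de=True)
            for i in range(n_lncrnas)
        ]
    )
    return hits, truth
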