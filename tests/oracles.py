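"""Independent reference implementations used only for cross-checking.

Each oracle recomputes a quantity by a different route than the package:
matrix-based GLS for contrasts, explicit ancestral-state enumeration for
the codon likelihood, path enumeration for stress centrality, plain loops
for TMM, hypergeometric sums for Fisher's test.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from scipy import linalg

from duinet.codon_model import SENSE_CODONS
from duinet.phylo import TaggedTree, _sorted_children


# -- GLS subtree oracle for independent contrasts ---------------------------


def _subtree_tips(node):
    return [l.taxon.label for l in node.leaf_iter()] if not node.is_leaf() else [
        node.taxon.label
    ]


def _subtree_cov(node):
    """BM covariance of subtree tips, process started at ``node``."""
    tips = []
    paths = {}

    def walk(n, acc):
        if n is not node:
            acc = acc + [n]
        if n.is_leaf():
            tips.append(n.taxon.label)
            paths[n.taxon.label] = acc
            return
        for c in n.child_nodes():
            walk(c, acc)

    walk(node, [])
    k = len(tips)
    C = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            shared = [
                e for e in paths[tips[i]] if e in paths[tips[j]]
            ]
            C[i, j] = sum(e.edge.length or 0.0 for e in shared)
    return tips, C


def _gls_root(node, values):
    """GLS estimate and variance of the subtree root state."""
    if node.is_leaf():
        return float(values[node.taxon.label]), 0.0
    tips, C = _subtree_cov(node)
    x = np.array([values[t] for t in tips])
    Cinv = linalg.inv(C)
    one = np.ones(len(tips))
    w = one @ Cinv
    est = float(w @ x / (w @ one))
    var = float(1.0 / (w @ one))
    return est, var


def gls_contrasts(tree: TaggedTree, values) -> np.ndarray:
    """Standardized contrasts via per-subtree GLS root estimation."""
    out = []
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            continue
        ci, cj = _sorted_children(node)
        xi, vi = _gls_root(ci, values)
        xj, vj = _gls_root(cj, values)
        bi = ci.edge.length or 0.0
        bj = cj.edge.length or 0.0
        out.append((xi - xj) / math.sqrt(bi + vi + bj + vj))
    return np.asarray(out)


# -- brute-force codon likelihood ------------------------------------------


def enumeration_codon_loglik(sequences, tree: TaggedTree, params, scale=1.0):
    """Explicit sum over all internal-state assignments (tiny trees only)."""
    from duinet.codon_model import CODON_INDEX, gy94_rate_matrix

    fg = set(tree.foreground_edges())
    nodes = list(tree.tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    n_states = len(SENSE_CODONS)
    P = {}
    for n in nodes:
        if n is tree.tree.seed_node:
            continue
        cls = "foreground" if n in fg else "background"
        q = gy94_rate_matrix(params, cls)
        P[n] = linalg.expm(q * (n.edge.length or 0.0) * scale)

    seq_codes = {
        lab: [CODON_INDEX[seq[i : i + 3]] for i in range(0, len(seq), 3)]
        for lab, seq in sequences.items()
    }
    n_sites = len(next(iter(seq_codes.values())))
    total = 0.0
    for site in range(n_sites):
        lik = 0.0
        for assign in itertools.product(range(n_states), repeat=len(internals)):
            state = dict(zip(internals, assign))
            for leaf in leaves:
                state[leaf] = seq_codes[leaf.taxon.label][site]
            term = params.freqs[state[tree.tree.seed_node]]
            for n in nodes:
                if n is tree.tree.seed_node:
                    continue
                term *= P[n][state[n.parent_node], state[n]]
            lik += term
        total += math.log(lik)
    return total


# -- stress centrality by path enumeration ----------------------------------


def stress_by_path_enumeration(graph: nx.Graph) -> dict:
    nodes = sorted(graph.nodes)
    stress = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        if not nx.has_path(graph, s, t):
            continue
        for path in nx.all_shortest_paths(graph, s, t):
            for v in path[1:-1]:
                stress[v] += 1.0
    return stress


# -- naive TMM ---------------------------------------------------------------


def naive_tmm_factors(counts_df, trim_M=0.30, trim_A=0.05, ref_sample=None):
    """Straight-line reimplementation of the trimmed weighted mean."""
    samples = list(counts_df.columns)
    lib = {s: float(counts_df[s].sum()) for s in samples}
    # reference: upper-quartile cpm closest to mean upper quartile
    uqs = {}
    for s in samples:
        cpms = sorted(c / lib[s] * 1e6 for c in counts_df[s])
        uqs[s] = _quantile(cpms, 0.75)
    mean_uq = sum(uqs.values()) / len(uqs)
    if ref_sample is None:
        ref_sample = min(samples, key=lambda s: (abs(uqs[s] - mean_uq), samples.index(s)))
    r = ref_sample

    factors = {}
    for s in samples:
        if s == r:
            factors[s] = 1.0
            continue
        Ms, As, ws = [], [], []
        for f in counts_df.index:
            cs, cr = float(counts_df.loc[f, s]), float(counts_df.loc[f, r])
            if cs <= 0 or cr <= 0:
                continue
            ps, pr = cs / lib[s], cr / lib[r]
            Ms.append(math.log2(ps / pr))
            As.append(0.5 * math.log2(ps * pr))
            ws.append(
                (lib[s] - cs) / (lib[s] * cs) + (lib[r] - cr) / (lib[r] * cr)
            )
        n = len(Ms)
        rM = _ranks(Ms)
        rA = _ranks(As)
        loM, hiM = math.floor(n * trim_M) + 1, n - math.floor(n * trim_M)
        loA, hiA = math.floor(n * trim_A) + 1, n - math.floor(n * trim_A)
        num = den = 0.0
        for i in range(n):
            if loM <= rM[i] <= hiM and loA <= rA[i] <= hiA:
                num += ws[i] * Ms[i]
                den += ws[i]
        factors[s] = 2 ** (num / den) if den > 0 else 1.0
    log_mean = sum(math.log(v) for v in factors.values()) / len(factors)
    return {s: v / math.exp(log_mean) for s, v in factors.items()}


def _quantile(sorted_vals, q):
    # linear interpolation, matching numpy's default
    n = len(sorted_vals)
    h = (n - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def _ranks(vals):
    """Average ranks (1-based) with ties, plain loops."""
    order = sorted(range(len(vals)), key=lambda i: vals[i])
    ranks = [0.0] * len(vals)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and vals[order[j + 1]] == vals[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


# -- Fisher exact two-sided by hypergeometric enumeration -------------------


def fisher_two_sided(a, b, c, d):
    """Sum of hypergeometric probabilities no larger than the observed."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def prob(x):
        return (
            math.comb(row1, x)
            * math.comb(n - row1, col1 - x)
            / math.comb(n, col1)
        )

    p_obs = prob(a)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    return sum(
        prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9)
    )


# -- Brownian tip values on a tree ------------------------------------------


def brownian_tips(tree: TaggedTree, rng, sigma2=1.0) -> dict:
    vals = {}
    h = {tree.tree.seed_node: 0.0}
    for nd in tree.tree.preorder_node_iter():
        if nd is not tree.tree.seed_node:
            b = nd.edge.length or 0.0
            h[nd] = h[nd.parent_node] + rng.normal(0.0, math.sqrt(sigma2 * b))
        if nd.is_leaf():
            vals[nd.taxon.label] = h[nd]
    return vals
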