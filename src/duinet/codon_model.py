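"""GY94 branch-model codon likelihoods and the two-ratio dN/dS test.

The substitution process is the Goldman–Yang codon model over the 61 sense
codons of the standard genetic code: instantaneous rate from codon *i* to
codon *j* is zero unless the codons differ at exactly one position, and
otherwise

    q_ij = pi_j * kappa^[transition] * omega_c^[nonsynonymous]

with ``omega_c`` depending on the branch class *c* (background vs
foreground).  Matrices are scaled so that the expected number of
substitutions per unit branch length equals one under the *background*
class, so foreground and background branch lengths live on the same scale.

The selection test compares a one-ratio model (single omega on every
branch) with a two-ratio model giving foreground branches — terminal
branches of foreground tips plus internal branches whose descendant tips
are all foreground — their own omega.  Branch lengths are taken from the
input tree and rescaled by one free scalar per model; the likelihood-ratio
statistic is referred to chi-square with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .phylo import TaggedTree

__all__ = [
    "SENSE_CODONS",
    "CODON_INDEX",
    "ModelParams",
    "SelectionResult",
    "gy94_rate_matrix",
    "codon_loglik",
    "branch_model_lrt",
    "f1x4_frequencies",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

def _build_code():
    # standard genetic code, codon -> amino acid ('*' = stop)
    code = {
        "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
        "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
        "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
        "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
        "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
        "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
        "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
        "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
        "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
        "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
        "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
        "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
        "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
        "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
        "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
        "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
    }
    return code


_TABLE = _build_code()

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in _TABLE if c not in _STOPS)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _neighbor_masks():
    """Single-step masks: (is_neighbor, is_transition, is_nonsyn) 61x61."""
    nb = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    ts = np.zeros_like(nb)
    ns = np.zeros_like(nb)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            nb[i, j] = True
            ts[i, j] = diffs[0] in _TRANSITIONS
            ns[i, j] = _TABLE[ci] != _TABLE[cj]
    return nb, ts, ns


_NB, _TS, _NS = _neighbor_masks()


@dataclass
class ModelParams:
    """GY94 parameters: kappa, per-class omega map, codon frequencies."""

    kappa: float
    omega: Mapping[str, float]  # keys: "background", "foreground"
    freqs: np.ndarray  # length 61, sums to 1

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        for cls, w in self.omega.items():
            if w < 0:
                raise ValueError(f"omega[{cls}] must be >= 0")
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (N_CODONS,) or not np.isclose(f.sum(), 1.0):
            raise ValueError("freqs must be length 61 and sum to 1")
        self.freqs = f


@dataclass
class SelectionResult:
    og_id: str
    lnL0: float
    lnL1: float
    lrt: float
    p: float
    omega_bg: float
    omega_fg: float
    delta_omega: float
    kappa0: float = np.nan
    kappa1: float = np.nan
    converged: bool = True


def uniform_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f1x4_frequencies(sequences: Mapping[str, str]) -> np.ndarray:
    """Empirical F1x4 codon frequencies from nucleotide composition."""
    counts = dict.fromkeys(_BASES, 0.0)
    for seq in sequences.values():
        for b in seq.upper():
            if b in counts:
                counts[b] += 1
    tot = sum(counts.values())
    if tot == 0:
        return uniform_frequencies()
    # floor to avoid zeros that break reversible symmetrization
    pb = {b: max(counts[b] / tot, 1e-6) for b in _BASES}
    f = np.array(
        [pb[c[0]] * pb[c[1]] * pb[c[2]] for c in SENSE_CODONS], dtype=float
    )
    return f / f.sum()


def _unscaled_q(kappa: float, omega: float, freqs: np.ndarray) -> np.ndarray:
    q = np.where(_NB, freqs[None, :], 0.0)
    q = q * np.where(_TS, kappa, 1.0) * np.where(_NS, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def gy94_rate_matrix(params: ModelParams, branch_class: str) -> np.ndarray:
    """Rate matrix for one branch class, background-scaled.

    Scaling divides by the expected substitution rate of the *background*
    class so a branch length of 1 means one expected substitution per codon
    under the background process.
    """
    q = _unscaled_q(params.kappa, params.omega[branch_class], params.freqs)
    q_bg = _unscaled_q(params.kappa, params.omega["background"], params.freqs)
    rate = -float(params.freqs @ np.diag(q_bg))
    if rate <= 0:
        raise ValueError("degenerate rate matrix (zero expected rate)")
    return q / rate


def _eig_reversible(q: np.ndarray, freqs: np.ndarray):
    """Eigendecomposition of a pi-reversible Q for fast expm(Q t)."""
    sq = np.sqrt(freqs)
    s = (q * sq[:, None]) / sq[None, :]
    s = 0.5 * (s + s.T)  # symmetrize numerically
    lam, vec = linalg.eigh(s)
    left = vec.T * sq[None, :]        # rows: V' Pi^{1/2}
    right = (vec.T / sq[None, :]).T   # Pi^{-1/2} V
    return lam, right, left


def transition_matrices(
    q: np.ndarray, freqs: np.ndarray, lengths: np.ndarray
) -> np.ndarray:
    """P(t) = expm(Q t) for a batch of branch lengths, via eigh."""
    lam, right, left = _eig_reversible(q, freqs)
    e = np.exp(np.outer(lengths, lam))  # (B, 61)
    p = np.einsum("ik,bk,kj->bij", right, e, left)
    return np.clip(p, 0.0, None)


# -- alignment handling ----------------------------------------------------


class CodonAlignmentError(ValueError):
    pass


def encode_alignment(sequences: Mapping[str, str]) -> dict[str, np.ndarray]:
    """Map label -> per-site codon index (-1 for gap/ambiguous codons)."""
    enc: dict[str, np.ndarray] = {}
    length = None
    for label, seq in sequences.items():
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3:
            raise CodonAlignmentError(
                f"sequence {label!r}: length {len(seq)} not divisible by 3"
            )
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise CodonAlignmentError("unequal sequence lengths")
        idx = np.empty(len(seq) // 3, dtype=np.int64)
        for k in range(0, len(seq), 3):
            codon = seq[k : k + 3]
            if codon in _STOPS:
                raise CodonAlignmentError(
                    f"in-frame stop codon {codon} in {label!r} at codon "
                    f"site {k // 3 + 1}"
                )
            idx[k // 3] = CODON_INDEX.get(codon, -1)
        enc[label] = idx
    return enc


def _site_patterns(enc: Mapping[str, np.ndarray], labels: Sequence[str]):
    mat = np.stack([enc[l] for l in labels], axis=0)  # (ntips, nsites)
    pats, counts = np.unique(mat, axis=1, return_counts=True)
    return pats, counts.astype(float)


def _edge_list(tree: TaggedTree):
    """Post-order (node, parent) pairs with branch lengths, root excluded."""
    edges = []
    for node in tree.tree.postorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        edges.append(node)
    return edges


def codon_loglik(
    sequences: Mapping[str, str],
    tree: TaggedTree,
    params: ModelParams,
    branch_scale: float = 1.0,
) -> float:
    """Felsenstein pruning log-likelihood of a codon alignment on a tree.

    Branch classes follow ``tree.foreground_edges()``; gaps/ambiguities are
    marginalized.  Site patterns are compressed before the recursion.
    """
    enc = encode_alignment(sequences)
    missing = set(l.taxon.label for l in tree.tree.leaf_node_iter()) - set(enc)
    if missing:
        raise CodonAlignmentError(f"tips without sequences: {sorted(missing)}")
    labels = [l.taxon.label for l in tree.tree.leaf_node_iter()]
    pats, counts = _site_patterns(enc, labels)
    return _loglik_from_patterns(pats, counts, labels, tree, params, branch_scale)


def _loglik_from_patterns(
    pats: np.ndarray,
    counts: np.ndarray,
    labels: Sequence[str],
    tree: TaggedTree,
    params: ModelParams,
    branch_scale: float,
) -> float:
    fg_nodes = set(tree.foreground_edges())
    edges = _edge_list(tree)
    lengths = np.array([(n.edge.length or 0.0) * branch_scale for n in edges])
    classes = np.array([n in fg_nodes for n in edges])

    p_all = np.empty((len(edges), N_CODONS, N_CODONS))
    for cls, mask in (("background", ~classes), ("foreground", classes)):
        if mask.any():
            q = gy94_rate_matrix(params, cls)
            p_all[mask] = transition_matrices(q, params.freqs, lengths[mask])

    npat = pats.shape[1]
    tip_row = {lab: i for i, lab in enumerate(labels)}
    partial: dict = {}
    for b, node in enumerate(edges + [tree.tree.seed_node]):
        if node.is_leaf():
            codes = pats[tip_row[node.taxon.label]]
            L = np.ones((npat, N_CODONS))
            obs = codes >= 0
            L[obs] = 0.0
            L[np.nonzero(obs)[0], codes[obs]] = 1.0
        else:
            L = np.ones((npat, N_CODONS))
            for child in node.child_nodes():
                L = L * partial.pop(child)
        if node is tree.tree.seed_node:
            site_lik = L @ params.freqs
            # guard underflow on long trees
            site_lik = np.maximum(site_lik, 1e-300)
            return float(counts @ np.log(site_lik))
        partial[node] = L @ p_all[b].T
    raise AssertionError("unreachable")


# -- fitting ----------------------------------------------------------------

_OMEGA_BOUNDS = (1e-4, 10.0)
_KAPPA_BOUNDS = (0.1, 20.0)
_SCALE_BOUNDS = (1e-3, 100.0)


@dataclass
class OptimizerConfig:
    n_starts: int = 2
    maxiter: int = 200
    tol: float = 1e-7
    seed: int = 0


def _fit(
    pats, counts, labels, tree, freqs, two_ratio: bool, cfg: OptimizerConfig,
    x0_list,
):
    nll_calls = {"n": 0}

    def nll(theta):
        kappa, *omegas, scale = np.exp(theta)
        omega = {"background": omegas[0]}
        omega["foreground"] = omegas[1] if two_ratio else omegas[0]
        params = ModelParams(kappa=kappa, omega=omega, freqs=freqs)
        nll_calls["n"] += 1
        return -_loglik_from_patterns(
            pats, counts, labels, tree, params, scale
        )

    lb = [np.log(_KAPPA_BOUNDS[0]), np.log(_OMEGA_BOUNDS[0])]
    ub = [np.log(_KAPPA_BOUNDS[1]), np.log(_OMEGA_BOUNDS[1])]
    if two_ratio:
        lb.append(np.log(_OMEGA_BOUNDS[0]))
        ub.append(np.log(_OMEGA_BOUNDS[1]))
    lb.append(np.log(_SCALE_BOUNDS[0]))
    ub.append(np.log(_SCALE_BOUNDS[1]))
    bounds = list(zip(lb, ub))

    best = None
    for x0 in x0_list:
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": cfg.maxiter, "ftol": cfg.tol},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def branch_model_lrt(
    sequences: Mapping[str, str],
    tree: TaggedTree,
    foreground: Iterable = None,
    config: OptimizerConfig | None = None,
    freqs: np.ndarray | None = None,
    og_id: str = "",
) -> SelectionResult:
    """One-ratio vs two-ratio (foreground omega) likelihood-ratio test.

    Returns log-likelihoods of both models, the LRT statistic
    ``2 (lnL1 - lnL0)`` with its chi-square(1) p-value, and
    ``delta_omega = omega_fg - omega_bg`` (negative means stronger
    purifying selection on foreground branches).
    """
    cfg = config or OptimizerConfig()
    if foreground is not None:
        tree = TaggedTree(
            tree.tree.clone(depth=1), foreground=foreground,
            subclass=tree.subclass,
        )
    if freqs is None:
        freqs = f1x4_frequencies(sequences)

    enc = encode_alignment(sequences)
    labels = [l.taxon.label for l in tree.tree.leaf_node_iter()]
    pats, counts = _site_patterns(enc, labels)

    fg_edges = tree.foreground_edges()
    rng = np.random.default_rng(cfg.seed)

    # null model: kappa, omega, scale
    starts0 = [np.log([2.0, 0.4, 1.0])]
    for _ in range(cfg.n_starts - 1):
        starts0.append(
            np.log(
                [
                    rng.uniform(1.0, 4.0),
                    rng.uniform(0.05, 1.5),
                    rng.uniform(0.5, 2.0),
                ]
            )
        )
    res0 = _fit(pats, counts, labels, tree, freqs, False, cfg, starts0)
    lnL0 = -res0.fun
    k0, w0, s0 = np.exp(res0.x)

    if not fg_edges:
        # model collapse: no foreground branch exists
        return SelectionResult(
            og_id=og_id, lnL0=lnL0, lnL1=lnL0, lrt=0.0, p=1.0,
            omega_bg=w0, omega_fg=w0, delta_omega=0.0,
            kappa0=k0, kappa1=k0, converged=bool(res0.success),
        )

    # alternative model warm-started from the null optimum (guarantees
    # lnL1 >= lnL0 up to optimizer tolerance) plus random restarts
    starts1 = [np.log([k0, w0, w0, s0])]
    for _ in range(cfg.n_starts - 1):
        starts1.append(
            np.log(
                [
                    k0,
                    w0,
                    np.clip(w0 * rng.uniform(0.2, 2.0), *_OMEGA_BOUNDS),
                    s0,
                ]
            )
        )
    res1 = _fit(pats, counts, labels, tree, freqs, True, cfg, starts1)
    lnL1 = -res1.fun
    k1, wbg, wfg, s1 = np.exp(res1.x)

    lrt = 2.0 * (lnL1 - lnL0)
    converged = bool(res0.success and res1.success) and lrt > -1e-6
    lrt = max(lrt, 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    return SelectionResult(
        og_id=og_id, lnL0=lnL0, lnL1=lnL1, lrt=lrt, p=p,
        omega_bg=wbg, omega_fg=wfg, delta_omega=wfg - wbg,
        kappa0=k0, kappa1=k1, converged=converged,
    )
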