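"""Egg sex-bias classification, CPM filtering, TMM normalization and
empirical-null differential-deposition calls.

The experimental design this stage models: unfertilized mussel egg pools
whose progeny sex ratio is scored by several operators from the paternal
mitochondria segregation pattern of sibling embryos.  Pools with a median
aggregated-pattern fraction >= 0.70 are "male-biased", pools with a median
dispersed fraction >= 0.70 are "female-biased".  Transcript counts from the
two groups are filtered (cpm >= 2 in at least one sample), TMM-normalized,
and tested for differential deposition with a nonparametric statistic:
per feature, the log2 ratio M and absolute difference D of group means are
compared against an empirical null built from within-feature sample
permutations; a feature is called when the fraction of null (M*, D*) pairs
it jointly dominates exceeds q = 0.95.  Called features are additionally
tested for Spearman correlation between normalized values and the
per-sample offspring sex ratio.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "classify_sex_bias",
    "cpm",
    "cpm_filter",
    "tmm_factors",
    "de_test",
    "sexratio_correlation",
]

MALE = "male_biased"
FEMALE = "female_biased"
UNASSIGNED = "unassigned"


@dataclass
class CountMatrix:
    """Integer feature x sample counts with per-sample egg metadata."""

    counts: pd.DataFrame  # features x samples, integer
    sex_ratios: pd.Series  # sigma_s in [0, 1] (fraction male-developing)
    groups: pd.Series  # bias label per sample

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.sex_ratios = self.sex_ratios.reindex(self.counts.columns)
        self.groups = self.groups.reindex(self.counts.columns)

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def classify_sex_bias(
    operator_ratios: Sequence[float], threshold: float = 0.70
) -> str:
    """Bias label from operator-scored aggregated-pattern fractions.

    The median across operators proxies the offspring sex ratio; the label
    is male_biased when median >= threshold, female_biased when
    (1 - median) >= threshold, otherwise unassigned.
    """
    ratios = np.asarray(list(operator_ratios), dtype=float)
    if ratios.size == 0:
        raise ValueError("need at least one operator ratio")
    if ((ratios < 0) | (ratios > 1)).any():
        raise ValueError("operator ratios must be in [0, 1]")
    m = float(np.median(ratios))
    if m >= threshold:
        return MALE
    if (1.0 - m) >= threshold:
        return FEMALE
    return UNASSIGNED


def cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    L = counts.sum(axis=0) if lib_sizes is None else lib_sizes
    return counts / L * 1e6


def cpm_filter(counts: pd.DataFrame, min_cpm: float = 2.0) -> pd.Index:
    """Features with cpm >= min_cpm in at least one sample.

    Library sizes are computed on the unfiltered matrix (paper's order).
    """
    c = cpm(counts)
    keep = (c >= min_cpm).any(axis=1)
    return counts.index[keep]


# -- TMM -------------------------------------------------------------------


def _choose_reference(counts: pd.DataFrame) -> str:
    c = cpm(counts)
    uq = c.quantile(0.75, axis=0)
    return (uq - uq.mean()).abs().idxmin()


def tmm_factors(
    counts: pd.DataFrame,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    ref_sample: str | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Trimmed-mean-of-M normalization factors and normalized matrix.

    Per sample, log ratios M against a reference sample (the one whose
    upper-quartile cpm is closest to the mean upper quartile) are doubly
    trimmed — 30% on M, 5% on A (average log abundance) — and averaged with
    inverse-variance weights; factors are rescaled to geometric mean one.
    The normalized matrix is cpm on effective library sizes ``L_s * f_s``.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    L = counts.sum(axis=0).astype(float)
    ref = ref_sample if ref_sample is not None else _choose_reference(counts)
    cr = counts[ref].to_numpy(dtype=float)
    Lr = float(L[ref])

    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        cs = counts[s].to_numpy(dtype=float)
        Ls = float(L[s])
        mask = (cs > 0) & (cr > 0)
        if not mask.any():
            raise ValueError(
                f"sample {s!r} shares no positive feature with reference"
            )
        ps, pr = cs[mask] / Ls, cr[mask] / Lr
        M = np.log2(ps / pr)
        A = 0.5 * np.log2(ps * pr)
        w = (Ls - cs[mask]) / (Ls * cs[mask]) + (Lr - cr[mask]) / (Lr * cr[mask])
        n = M.size
        rM = stats.rankdata(M)
        rA = stats.rankdata(A)
        loM, hiM = np.floor(n * trim_M) + 1, n - np.floor(n * trim_M)
        loA, hiA = np.floor(n * trim_A) + 1, n - np.floor(n * trim_A)
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if not keep.any() or w[keep].sum() == 0:
            factors[s] = 1.0
        else:
            factors[s] = float(2 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep])))
    f = pd.Series(factors).reindex(counts.columns)
    f = f / np.exp(np.log(f).mean())  # geometric mean 1
    norm = counts / (L * f) * 1e6
    return f, norm


# -- differential deposition ------------------------------------------------


def _split_masks(n: int, n_a: int, n_null: int, rng) -> np.ndarray:
    """Boolean (K, n) masks assigning n_a samples to group A.

    All balanced splits are enumerated when their number is at most
    ``n_null``; otherwise ``n_null`` random splits are drawn.  The first
    row is always the observed assignment (first n_a columns)."""
    from math import comb

    observed = np.zeros(n, dtype=bool)
    observed[:n_a] = True
    if comb(n, n_a) <= n_null:
        masks = []
        for idx in itertools.combinations(range(n), n_a):
            m = np.zeros(n, dtype=bool)
            m[list(idx)] = True
            masks.append(m)
        masks = np.array(masks)
        # move the observed split to the front
        obs_pos = int(np.nonzero((masks == observed).all(axis=1))[0][0])
        masks[[0, obs_pos]] = masks[[obs_pos, 0]]
        return masks
    picks = np.argsort(rng.random((n_null - 1, n)), axis=1)[:, :n_a]
    masks = np.zeros((n_null, n), dtype=bool)
    masks[0] = observed
    for i, row in enumerate(picks):
        masks[i + 1, row] = True
    return masks


def de_test(
    norm: pd.DataFrame,
    groups: Sequence[str],
    n_null: int = 100_000,
    q: float = 0.95,
    pseudo: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical-null differential deposition calls on normalized values.

    Per feature: M = log2 ratio and D = absolute difference of the two
    group means (pseudo-count stabilizes M at zeros).  The null re-splits
    the feature's own samples into balanced pseudo-groups (all balanced
    splits when few, random ones otherwise) and recomputes (M*, D*);
    ``prob`` is the fraction of the feature's null pairs strictly
    dominated (|M*| < |M| and D* < D) and a feature is called when
    prob > q; the complementary exceedance fraction counts the observed
    split itself, which keeps the call rate conservative under the null.
    Ranking each feature against its own resplit null keeps the call
    criterion free of the between-feature abundance scale.
    """
    groups = np.asarray(list(groups))
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("need exactly two group levels")
    if min((groups == g).sum() for g in levels) < 2:
        raise ValueError("need at least two samples per group")
    order = np.concatenate(
        [np.nonzero(groups == levels[0])[0], np.nonzero(groups == levels[1])[0]]
    )
    x = norm.to_numpy(dtype=float)[:, order]
    n = x.shape[1]
    n_a = int((groups == levels[0]).sum())
    rng = np.random.default_rng(seed)
    masks = _split_masks(n, n_a, n_null, rng)
    if masks.shape[0] < 1.0 / (1.0 - q):
        raise ValueError(
            f"{masks.shape[0]} null splits cannot resolve q={q}; "
            "increase n_null or sample size"
        )

    w_a = masks.T.astype(float) / n_a  # (n, K)
    w_b = (~masks).T.astype(float) / (n - n_a)
    prob = np.empty(x.shape[0])
    M = np.empty(x.shape[0])
    D = np.empty(x.shape[0])
    block = 2048
    for lo in range(0, x.shape[0], block):
        xb = x[lo : lo + block]
        ma = xb @ w_a  # (F, K) group-A means per split
        mb = xb @ w_b
        Ms = np.log2((ma + pseudo) / (mb + pseudo))
        Ds = np.abs(ma - mb)
        M[lo : lo + block] = Ms[:, 0]
        D[lo : lo + block] = Ds[:, 0]
        # strict dominance: the complement (|M*| >= |M| or D* >= D)
        # includes the observed split itself, keeping calls conservative
        dominated = (np.abs(Ms) < np.abs(Ms[:, [0]])) & (Ds < Ds[:, [0]])
        prob[lo : lo + block] = dominated.mean(axis=1)

    called = prob > q
    direction = np.where(M > 0, str(levels[0]), str(levels[1]))
    direction = np.where(M == 0, "none", direction)
    return pd.DataFrame(
        {
            "M": M,
            "D": D,
            "prob": prob,
            "called": called,
            "direction": direction,
        },
        index=norm.index,
    )


# -- sex-ratio correlation ---------------------------------------------------


@lru_cache(maxsize=8)
def _exact_rho_null(n: int) -> np.ndarray:
    """Null distribution of Spearman rho for untied data, sample size n."""
    ident = np.arange(n)
    denom = n * (n * n - 1)
    rhos = []
    for perm in itertools.permutations(range(n)):
        d2 = int(np.sum((np.asarray(perm) - ident) ** 2))
        rhos.append(1.0 - 6.0 * d2 / denom)
    return np.sort(np.asarray(rhos))


def sexratio_correlation(
    values: Sequence[float], sigma: Sequence[float]
) -> tuple[float, float]:
    """Spearman correlation of normalized values with offspring sex ratio.

    Exact permutation p for n <= 9 without ties; asymptotic otherwise.
    Returns (rho, p); rho is NaN for constant input.
    """
    x = np.asarray(list(values), dtype=float)
    y = np.asarray(list(sigma), dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p_asym = stats.spearmanr(x, y)
    n = x.size
    no_ties = len(set(x)) == n and len(set(y)) == n
    if n <= 9 and no_ties:
        null = _exact_rho_null(n)
        tol = 1e-12
        p = float(np.mean(np.abs(null) >= abs(rho) - tol))
        return float(rho), p
    return float(rho), float(p_asym)
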