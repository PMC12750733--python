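"""Evolutionary rate covariation (ERC) with the mitochondrial tree.

For each gene tree, species root-to-tip distances of the gene tree and of
the mitochondrial tree are computed on their shared species, adjusted for
phylogenetic non-independence via independent contrasts on the reference
species tree, and regressed through the origin (the standard choice for
contrasts).  A significant positive association is the coevolution proxy.

The module also provides the 2x2 enrichment test used to ask whether
significant ERC is over-represented among a focal gene set (e.g. the
convergently evolving genes), via chi-square or Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import TaggedTree, pic_contrasts, root_to_tip

__all__ = ["ERCResult", "erc_test", "enrichment_2x2"]


@dataclass
class ERCResult:
    gene_id: str
    n_shared_species: int
    slope: float
    correlation: float
    p: float

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p) and self.p < 0.05


class InsufficientOverlap(ValueError):
    """Gene skipped: too few species shared with the mitochondrial tree."""


def _origin_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, correlation and two-sided p of y ~ x through the origin.

    The t statistic uses n - 1 residual degrees of freedom (one slope, no
    intercept).
    """
    sxx = float(x @ x)
    if sxx == 0:
        return np.nan, np.nan, np.nan
    beta = float(x @ y) / sxx
    resid = y - beta * x
    n = x.size
    df = n - 1
    s2 = float(resid @ resid) / df if df > 0 else np.nan
    syy = float(y @ y)
    corr = float(x @ y) / np.sqrt(sxx * syy) if syy > 0 else np.nan
    if not np.isfinite(s2) or s2 == 0:
        p = 0.0 if beta != 0 else 1.0
    else:
        t = beta / np.sqrt(s2 / sxx)
        p = float(2.0 * stats.t.sf(abs(t), df))
    return beta, corr, p


def erc_test(
    gene_tree: TaggedTree,
    mito_tree: TaggedTree,
    ref_tree: TaggedTree,
    min_shared: int = 10,
    gene_id: str = "",
) -> ERCResult:
    """PIC-adjusted root-to-tip regression of gene on mitochondrial rates."""
    shared = (
        set(gene_tree.tip_labels)
        & set(mito_tree.tip_labels)
        & set(ref_tree.tip_labels)
    )
    if len(shared) < min_shared:
        raise InsufficientOverlap(
            f"{gene_id or 'gene'}: {len(shared)} shared species < {min_shared}"
        )
    d_gene = {s: v for s, v in gene_tree.prune_to(shared).root_to_tip().items()}
    d_mito = {s: v for s, v in mito_tree.prune_to(shared).root_to_tip().items()}
    ref = ref_tree.prune_to(shared)
    u_gene = pic_contrasts(ref, d_gene)
    u_mito = pic_contrasts(ref, d_mito)
    beta, corr, p = _origin_regression(u_mito, u_gene)
    return ERCResult(
        gene_id=gene_id,
        n_shared_species=len(shared),
        slope=beta,
        correlation=corr,
        p=p,
    )


def enrichment_2x2(
    focal: Iterable,
    flagged: Iterable,
    universe: Iterable,
    method: str = "chi_square",
) -> dict:
    """Association between focal membership and a flag over a universe.

    Builds the 2x2 table {focal, non-focal} x {flagged, non-flagged} and
    tests it with chi-square (no continuity correction) or Fisher's exact
    test.  Degenerate margins refuse the chi-square and force Fisher.
    """
    universe = set(universe)
    focal = set(focal) & universe
    flagged = set(flagged) & universe
    a = len(focal & flagged)
    b = len(focal - flagged)
    c = len(flagged - focal)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)

    degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    if method == "chi_square":
        if degenerate:
            raise ValueError(
                "degenerate margin: chi-square undefined, use fisher_exact"
            )
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    elif method == "fisher_exact":
        stat, p = stats.fisher_exact(table, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"statistic": float(stat), "p": float(p), "table": table.astype(int)}


def erc_frame(results: Iterable[ERCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "n_shared_species": r.n_shared_species,
                "slope": r.slope,
                "correlation": r.correlation,
                "p": r.p,
            }
            for r in results
        ]
    )
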