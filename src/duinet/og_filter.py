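"""Orthogroup retention, subclass-monophyly validation and trimming.

Candidate single-copy orthogroups (OGs) pass three rules before any
evolutionary analysis:

* alignment trimming — columns missing/gapped in more than half the
  species are removed, then sequences that are more than 80% gap in the
  trimmed alignment;
* subclass monophyly — the gene tree must keep the three bivalve
  subclasses monophyletic (tested on the unrooted topology); when one or
  two species alone break monophyly they are removed and the OG is marked
  "rescued";
* representativeness — at least 15 species, at least 4 foreground (DUI)
  species.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .phylo import TaggedTree

__all__ = [
    "OrthoGroup",
    "MonophylyResult",
    "trim_alignment",
    "check_subclass_monophyly",
    "filter_orthogroups",
]

GAP_CHARS = set("-?.XxNn*")


@dataclass
class OrthoGroup:
    og_id: str
    sequences: dict[str, str]  # species -> aligned sequence
    rescued_species: tuple[str, ...] = ()

    def __post_init__(self):
        lens = {len(s) for s in self.sequences.values()}
        if len(lens) > 1:
            raise ValueError(f"{self.og_id}: unequal sequence lengths {lens}")

    @property
    def species(self) -> set[str]:
        return set(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def is_empty(self) -> bool:
        return not self.sequences or self.n_columns == 0


def _is_gap(ch: str) -> bool:
    return ch in GAP_CHARS


def trim_alignment(
    og: OrthoGroup,
    max_column_missing: float = 0.5,
    max_seq_gap: float = 0.8,
    all_species: Iterable[str] | None = None,
) -> tuple[OrthoGroup, list[int], list[str]]:
    """Column trim then sequence trim; returns both removal lists.

    A column is removed when its missing fraction exceeds
    ``max_column_missing``; with ``all_species`` given, species absent from
    the OG count as missing in every column (gaps and absence are treated
    identically), otherwise the denominator is the number of sequences
    present.  Sequences whose gap fraction in the trimmed alignment
    exceeds ``max_seq_gap`` are then removed.
    """
    if og.is_empty():
        raise ValueError(f"{og.og_id}: empty alignment")
    labels = sorted(og.sequences)
    seqs = [og.sequences[l] for l in labels]
    ncol = len(seqs[0])
    denom = len(set(all_species)) if all_species is not None else len(seqs)
    n_absent = denom - len(seqs)

    kept_cols, dropped_cols = [], []
    for j in range(ncol):
        missing = n_absent + sum(_is_gap(s[j]) for s in seqs)
        if missing / denom > max_column_missing:
            dropped_cols.append(j)
        else:
            kept_cols.append(j)

    trimmed = {
        lab: "".join(seq[j] for j in kept_cols)
        for lab, seq in zip(labels, seqs)
    }
    dropped_seqs = []
    if kept_cols:
        for lab in labels:
            gapfrac = sum(_is_gap(c) for c in trimmed[lab]) / len(kept_cols)
            if gapfrac > max_seq_gap:
                dropped_seqs.append(lab)
        for lab in dropped_seqs:
            del trimmed[lab]
    else:
        trimmed = {}
    out = OrthoGroup(og.og_id, trimmed, rescued_species=og.rescued_species)
    return out, dropped_cols, dropped_seqs


@dataclass
class MonophylyResult:
    status: str  # "pass" | "fail"
    offending_species: frozenset = frozenset()

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def _splits(tree: TaggedTree) -> list[frozenset]:
    """Tip sets below each edge of the (rooted representation of the) tree."""
    below: dict = {}
    out = []
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(
                *(below[c] for c in node.child_nodes())
            )
        if node is not tree.tree.seed_node:
            out.append(below[node])
    return out


def _all_monophyletic(
    splits: Sequence[frozenset],
    keep: frozenset,
    groups: Mapping[str, frozenset],
) -> bool:
    """Are all groups monophyletic on the tree restricted to ``keep``?

    Uses the fact that the splits of a restricted unrooted tree are the
    restrictions of the original splits.
    """
    for members in groups.values():
        g = members & keep
        if len(g) <= 1 or g == keep:
            continue  # vacuously monophyletic
        comp = keep - g
        ok = False
        for s in splits:
            r = s & keep
            if r == g or r == comp:
                ok = True
                break
        if not ok:
            return False
    return True


def check_subclass_monophyly(gene_tree: TaggedTree) -> MonophylyResult:
    """Unrooted monophyly of the three subclasses, with 1-2 species rescue.

    On failure, ``offending_species`` is a minimum set of at most two
    species whose removal restores monophyly of every subclass (empty when
    no such small fix exists).
    """
    tips = frozenset(gene_tree.tip_labels)
    groups: dict[str, set] = {}
    for tip in tips:
        sub = gene_tree.subclass.get(tip)
        if sub is None:
            raise ValueError(f"tip {tip!r} has no subclass label")
        groups.setdefault(sub, set()).add(tip)
    groups = {k: frozenset(v) for k, v in groups.items()}
    if len(groups) < 3:
        warnings.warn(
            "fewer than three subclasses represented: vacuous pass",
            stacklevel=2,
        )
        return MonophylyResult("pass")

    splits = _splits(gene_tree)
    if _all_monophyletic(splits, tips, groups):
        return MonophylyResult("pass")

    tip_list = sorted(tips)
    for size in (1, 2):
        for combo in itertools.combinations(tip_list, size):
            keep = tips - set(combo)
            if _all_monophyletic(splits, keep, groups):
                return MonophylyResult("fail", frozenset(combo))
    return MonophylyResult("fail", frozenset())


def filter_orthogroups(
    ogs: Sequence[OrthoGroup],
    foreground: Iterable[str],
    min_species: int = 15,
    min_foreground: int = 4,
) -> list[OrthoGroup]:
    """OGs with >= min_species species and >= min_foreground foreground."""
    fg = set(foreground)
    kept = []
    for og in ogs:
        if len(og.species) >= min_species and len(og.species & fg) >= min_foreground:
            kept.append(og)
    return kept


def retention_report(
    ogs: Sequence[OrthoGroup],
    retained: Sequence[OrthoGroup],
    foreground: Iterable[str],
) -> pd.DataFrame:
    fg = set(foreground)
    kept_ids = {og.og_id for og in retained}
    rows = []
    for og in ogs:
        rows.append(
            {
                "og_id": og.og_id,
                "n_species": len(og.species),
                "n_foreground": len(og.species & fg),
                "status": "retained" if og.og_id in kept_ids else "discarded",
                "rescued_species": ",".join(sorted(og.rescued_species)),
            }
        )
    return pd.DataFrame(rows)
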