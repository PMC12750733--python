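"""Tree containers, Newick I/O, root-to-tip distances and independent contrasts.

Shared machinery for the convergence and evolutionary-rate-covariation
stages.  Trees are held as rooted :class:`dendropy.Tree` objects wrapped in
:class:`TaggedTree`, which additionally carries the foreground (DUI) flag
and the taxonomic subclass label of every tip.

Phylogenetic independent contrasts (PIC) follow Felsenstein's recursion:
at an internal node whose children carry values ``x_i, x_j`` on adjusted
branch lengths ``v_i, v_j`` the standardized contrast is
``(x_i - x_j) / sqrt(v_i + v_j)``; the node receives the precision-weighted
mean of its children and its parent edge is lengthened by
``v_i * v_j / (v_i + v_j)``.  Under Brownian motion on the tree the
contrasts are i.i.d. normal, which is what makes them suitable inputs for
ordinary regression in the rate-covariation stage.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy
import numpy as np

__all__ = [
    "NewickError",
    "TaggedTree",
    "parse_newick",
    "write_newick",
    "root_to_tip",
    "pic_contrasts",
]

#: added to zero-length terminal branches before PIC (see docs/methods.md)
TERMINAL_EPSILON = 1e-8


class NewickError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate labels...)."""


class TaggedTree:
    """Rooted tree with branch lengths plus per-tip foreground/subclass tags.

    Parameters
    ----------
    tree:
        A rooted ``dendropy.Tree``.  Branch lengths may be ``None`` on the
        root edge; everywhere else they are treated as 0 when missing.
    foreground:
        Tip labels flagged as foreground (DUI) species.
    subclass:
        Optional mapping tip label -> subclass name (three bivalve
        subclasses in the motivating analysis).
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        foreground: Iterable[str] = (),
        subclass: Mapping[str, str] | None = None,
    ):
        self.tree = tree
        self.foreground = frozenset(foreground)
        self.subclass = dict(subclass or {})
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            seen, dup = set(), None
            for lab in labels:
                if lab in seen:
                    dup = lab
                    break
                seen.add(lab)
            raise NewickError(f"duplicate tip label: {dup!r}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        text: str,
        foreground: Iterable[str] = (),
        subclass: Mapping[str, str] | None = None,
    ) -> "TaggedTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                rooting="force-rooted",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickError(f"cannot parse Newick: {exc}") from exc
        return cls(tree, foreground=foreground, subclass=subclass)

    def clone(self) -> "TaggedTree":
        return TaggedTree(
            self.tree.clone(depth=1), self.foreground, dict(self.subclass)
        )

    # -- basic accessors ---------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def background(self) -> frozenset:
        return frozenset(self.tip_labels) - self.foreground

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".10g",
        )
        return s.strip() + "\n"

    # -- operations --------------------------------------------------------

    def root_to_tip(self) -> dict[str, float]:
        """Sum of branch lengths on the path root -> tip, per tip."""
        dist: dict[str, float] = {}
        depth = {self.tree.seed_node: 0.0}
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
            if node.is_leaf():
                dist[node.taxon.label] = depth[node]
        if self.tree.seed_node.is_leaf():
            dist[self.tree.seed_node.taxon.label] = 0.0
        return dist

    def prune_to(self, taxa: Iterable[str]) -> "TaggedTree":
        """Restriction of the tree to ``taxa`` (path lengths preserved)."""
        keep = set(taxa)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        sub = self.tree.extract_tree_with_taxa_labels(keep)
        # the extracted tree shares the source namespace; detach before
        # purging so the source tree is left untouched
        sub.migrate_taxon_namespace(dendropy.TaxonNamespace())
        # collapse unifurcations left at the root so the tree stays binary
        sub.suppress_unifurcations()
        return TaggedTree(
            sub,
            foreground=self.foreground & keep,
            subclass={k: v for k, v in self.subclass.items() if k in keep},
        )

    def foreground_edges(self, include_stem: bool = False):
        """Edges assigned to the foreground class.

        Terminal edges of foreground tips plus internal edges all of whose
        descendant tips are foreground (the "DUI species clades"
        convention).  With ``include_stem`` the stem edge of each maximal
        foreground clade is already covered by this rule; the flag is kept
        for interface compatibility and currently has no additional effect.
        """
        fg_nodes = []
        all_fg: dict[dendropy.Node, bool] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                all_fg[node] = node.taxon.label in self.foreground
            else:
                all_fg[node] = all(all_fg[c] for c in node.child_nodes())
            if node is not self.tree.seed_node and all_fg[node]:
                fg_nodes.append(node)
        return fg_nodes


# -- module-level functional interface ------------------------------------


def parse_newick(
    text: str,
    foreground: Iterable[str] = (),
    subclass: Mapping[str, str] | None = None,
) -> TaggedTree:
    return TaggedTree.from_newick(text, foreground=foreground, subclass=subclass)


def write_newick(tree: TaggedTree) -> str:
    return tree.to_newick()


def root_to_tip(tree: TaggedTree) -> dict[str, float]:
    return tree.root_to_tip()


def _sorted_children(node) -> list:
    """Deterministic child order: by smallest descendant tip label."""

    def key(child):
        if child.is_leaf():
            return child.taxon.label
        return min(l.taxon.label for l in child.leaf_iter())

    return sorted(node.child_nodes(), key=key)


def pic_contrasts(
    ref_tree: TaggedTree, values: Mapping[str, float]
) -> np.ndarray:
    """Standardized phylogenetic independent contrasts of tip values.

    Tips of ``ref_tree`` absent from ``values`` are pruned first.  Contrasts
    are returned in deterministic post-order (children ordered by smallest
    descendant label), one per internal node with two children.

    Raises
    ------
    ValueError
        If an internal cherry has total adjusted branch length zero (the
        contrast is undefined); zero-length *terminal* branches are instead
        nudged by ``TERMINAL_EPSILON``.
    """
    species = set(values)
    tips = set(ref_tree.tip_labels)
    if not species >= tips:
        ref_tree = ref_tree.prune_to(species & tips)
    if ref_tree.n_tips < 2:
        raise ValueError("need at least 2 tips with values for contrasts")

    x: dict = {}
    v: dict = {}
    contrasts: list[float] = []
    for node in ref_tree.tree.postorder_node_iter():
        edge_len = node.edge.length or 0.0
        if node.is_leaf():
            if edge_len <= 0.0:
                edge_len = TERMINAL_EPSILON
            x[node] = float(values[node.taxon.label])
            v[node] = edge_len
            continue
        children = _sorted_children(node)
        if len(children) != 2:
            raise ValueError(
                "contrasts require a binary tree; node with "
                f"{len(children)} children encountered"
            )
        ci, cj = children
        vi, vj = v[ci], v[cj]
        if vi + vj <= 0.0:
            raise ValueError(
                "zero-length cherry: contrast undefined; lengthen terminal "
                "branches (epsilon policy) before calling pic_contrasts"
            )
        contrasts.append((x[ci] - x[cj]) / np.sqrt(vi + vj))
        x[node] = (x[ci] / vi + x[cj] / vj) / (1.0 / vi + 1.0 / vj)
        v[node] = edge_len + vi * vj / (vi + vj)
    return np.asarray(contrasts, dtype=float)


def write_tip_values(values: Mapping[str, float], path) -> None:
    """Two-column TSV (species, value)."""
    with open(path, "w") as fh:
        fh.write("species\tvalue\n")
        for sp in sorted(values):
            fh.write(f"{sp}\t{values[sp]:.10g}\n")


def read_tip_values(path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            sp, val = line.rstrip("\n").split("\t")
            out[sp] = float(val)
    return out
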