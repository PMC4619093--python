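"""GmrS/GmrD coevolution: support collapsing, counterpart pruning, congruence.

The coevolution analysis compares the phylogeny of GmrS domains with that of
GmrD domains.  Splits with low local (SH-like) support are collapsed into
polytomies, leaves without an assigned counterpart in the other tree are
removed, and the two trees — with leaves identified through the GmrS<->GmrD
association — are compared as unrooted split sets.  The congruence statistic
is the Robinson-Foulds distance over non-trivial splits, with polytomies
compared as observed (no resolution is injected).
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import dendropy

__all__ = [
    "SupportedTree",
    "Association",
    "CongruenceReport",
    "collapse_low_support",
    "prune_unpaired",
    "congruence",
    "coevolution_analysis",
    "tanglegram_export",
    "read_tanglegram",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Association:
    """Bijective partial map between GmrS-tree leaves and GmrD-tree leaves.

    Each pair is tagged with its source: ``double`` (two domains of one
    fusion protein) or ``merged`` (a predicted single-domain pair).
    """

    pairs: tuple[tuple[str, str], ...]
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        s_leaves = [s for s, _ in self.pairs]
        d_leaves = [d for _, d in self.pairs]
        if len(set(s_leaves)) != len(s_leaves) or len(set(d_leaves)) != len(d_leaves):
            raise ValueError("a leaf appears twice in the association")
        if self.sources and len(self.sources) != len(self.pairs):
            raise ValueError("sources must be empty or match pairs in length")

    def __len__(self) -> int:
        return len(self.pairs)

    def s_leaves(self) -> set[str]:
        return {s for s, _ in self.pairs}

    def d_leaves(self) -> set[str]:
        return {d for _, d in self.pairs}

    def pair_id(self) -> dict[str, str]:
        """Map every leaf (either side) to a canonical pair identifier."""
        out: dict[str, str] = {}
        for s, d in self.pairs:
            pid = f"{s}|{d}"
            out[s] = pid
            out[d] = pid
        return out


class SupportedTree:
    """A phylogenetic tree with per-split support values in [0, 1].

    Supports are read from Newick internal-node labels; if any parsed value
    exceeds 1 the whole tree is assumed to use the percentage dialect and
    every support is rescaled by 1/100.  Trees are treated as unrooted for
    split comparison.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    @classmethod
    def from_newick(cls, newick: str) -> "SupportedTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        supports: list[tuple[dendropy.Node, float | None]] = []
        any_over_one = False
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            val: float | None = None
            if node.label is not None:
                try:
                    val = float(node.label)
                except ValueError:
                    val = None
            if val is not None and val > 1.0:
                any_over_one = True
            supports.append((node, val))
        for node, val in supports:
            if val is not None and any_over_one:
                val /= 100.0
            node.support = val  # type: ignore[attr-defined]
        return cls(tree)

    @classmethod
    def read(cls, path: str | Path) -> "SupportedTree":
        return cls.from_newick(Path(path).read_text())

    def to_newick(self) -> str:
        for node in self.tree.preorder_node_iter():
            if not node.is_leaf() and node.parent_node is not None:
                sup = getattr(node, "support", None)
                node.label = None if sup is None else f"{sup:.4f}"
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def leaf_labels(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter() if leaf.taxon}

    def clone(self) -> "SupportedTree":
        return SupportedTree.from_newick(self.to_newick())

    def splits(self, rename: dict[str, str] | None = None) -> set[frozenset[frozenset[str]]]:
        """Non-trivial unrooted bipartitions as two-sided frozensets."""
        labels = self.leaf_labels()
        if rename:
            labels = {rename.get(l, l) for l in labels}
        out: set[frozenset[frozenset[str]]] = set()
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = {
                leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon
            }
            if rename:
                below = {rename.get(l, l) for l in below}
            rest = labels - below
            if len(below) >= 2 and len(rest) >= 2:
                out.add(frozenset({frozenset(below), frozenset(rest)}))
        return out


@dataclass(frozen=True)
class CongruenceReport:
    rf: int
    rf_normalized: float
    n_shared_pairs: int
    n_pruned_s: int
    n_pruned_d: int

    def __post_init__(self) -> None:
        if self.rf < 0 or not 0.0 <= self.rf_normalized <= 1.0:
            raise ValueError("invalid congruence report")


def collapse_low_support(tree: SupportedTree, threshold: float = 0.8) -> SupportedTree:
    """Collapse internal splits with support strictly below ``threshold``.

    A split with support exactly at the threshold is retained.  Splits with
    missing support are collapsed (conservative) and logged.  The leaf set is
    unchanged; the operation is idempotent.
    """
    out = tree.clone()
    to_collapse = []
    for node in out.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        sup = getattr(node, "support", None)
        if sup is None:
            logger.warning("internal split without support value: collapsing")
            to_collapse.append(node)
        elif sup < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out


def prune_unpaired(
    tree_s: SupportedTree, tree_d: SupportedTree, assoc: Association
) -> tuple[SupportedTree, SupportedTree]:
    """Remove leaves for which no counterpart could be assigned.

    Each output tree contains exactly the leaves appearing in the
    association; degree-2 nodes created by pruning are suppressed.
    """
    if len(assoc) == 0:
        warnings.warn("empty association: both pruned trees are empty")

    def prune(tree: SupportedTree, keep: set[str]) -> SupportedTree:
        out = tree.clone()
        taxa = [t for t in out.tree.taxon_namespace if t.label in keep]
        if not taxa:
            return SupportedTree(dendropy.Tree())
        out.tree.retain_taxa(taxa)
        return out

    return prune(tree_s, assoc.s_leaves()), prune(tree_d, assoc.d_leaves())


def congruence(
    tree_s: SupportedTree,
    tree_d: SupportedTree,
    assoc: Association,
    n_pruned_s: int = 0,
    n_pruned_d: int = 0,
) -> CongruenceReport:
    """Robinson-Foulds congruence of two counterpart-pruned trees.

    Leaves are relabeled by association pair id; ``rf`` counts non-trivial
    splits present in exactly one tree, and ``rf_normalized`` divides by the
    total number of non-trivial splits in both trees (0 when both trees are
    stars).  Multifurcations are compared as observed.
    """
    rename = assoc.pair_id()
    s_labels = {rename.get(l, l) for l in tree_s.leaf_labels()}
    d_labels = {rename.get(l, l) for l in tree_d.leaf_labels()}
    if s_labels != d_labels:
        raise ValueError("leaf sets differ after relabeling by association")
    splits_s = tree_s.splits(rename=rename)
    splits_d = tree_d.splits(rename=rename)
    rf = len(splits_s ^ splits_d)
    denom = len(splits_s) + len(splits_d)
    return CongruenceReport(
        rf=rf,
        rf_normalized=(rf / denom) if denom else 0.0,
        n_shared_pairs=len(assoc),
        n_pruned_s=n_pruned_s,
        n_pruned_d=n_pruned_d,
    )


def coevolution_analysis(
    tree_s: SupportedTree,
    tree_d: SupportedTree,
    assoc: Association,
    support_threshold: float = 0.8,
) -> tuple[SupportedTree, SupportedTree, CongruenceReport]:
    """Collapse low-support splits, prune unpaired leaves, score congruence."""
    cs = collapse_low_support(tree_s, support_threshold)
    cd = collapse_low_support(tree_d, support_threshold)
    n_s = len(cs.leaf_labels())
    n_d = len(cd.leaf_labels())
    ps, pd = prune_unpaired(cs, cd, assoc)
    report = congruence(
        ps,
        pd,
        assoc,
        n_pruned_s=n_s - len(ps.leaf_labels()),
        n_pruned_d=n_d - len(pd.leaf_labels()),
    )
    return ps, pd, report


def tanglegram_export(
    tree_s: SupportedTree,
    tree_d: SupportedTree,
    assoc: Association,
    out_dir: str | Path,
    prefix: str = "tanglegram",
) -> dict[str, Path]:
    """Write the paired trees and their leaf associations for external viewers.

    Emits ``<prefix>_s.nwk``, ``<prefix>_d.nwk`` and ``<prefix>_links.tsv``
    (columns s_leaf, d_leaf, source); round-trips through
    :func:`read_tanglegram`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree_s": out / f"{prefix}_s.nwk",
        "tree_d": out / f"{prefix}_d.nwk",
        "links": out / f"{prefix}_links.tsv",
    }
    tree_s.write(paths["tree_s"])
    tree_d.write(paths["tree_d"])
    sources = assoc.sources or tuple("double" for _ in assoc.pairs)
    with open(paths["links"], "w") as fh:
        fh.write("s_leaf\td_leaf\tsource\n")
        for (s, d), src in zip(assoc.pairs, sources):
            fh.write(f"{s}\t{d}\t{src}\n")
    return paths


def read_tanglegram(
    out_dir: str | Path, prefix: str = "tanglegram"
) -> tuple[SupportedTree, SupportedTree, Association]:
    out = Path(out_dir)
    tree_s = SupportedTree.read(out / f"{prefix}_s.nwk")
    tree_d = SupportedTree.read(out / f"{prefix}_d.nwk")
    pairs: list[tuple[str, str]] = []
    sources: list[str] = []
    with open(out / f"{prefix}_links.tsv") as fh:
        next(fh)
        for line in fh:
            if not line.strip():
                continue
            s, d, src = line.rstrip("\n").split("\t")
            pairs.append((s, d))
            sources.append(src)
    return tree_s, tree_d, Association(tuple(pairs), tuple(sources))
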