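"""Rooted tree container built on dendropy, with lossless Newick round-trips."""

from __future__ import annotations

from typing import Iterable, Optional

import dendropy


class PhyloTree:
    """A rooted species or gene tree with uniquely named leaves.

    Thin wrapper over :class:`dendropy.Tree` that enforces the package's
    invariants (single root, unique leaf names) and fixes serialization
    conventions (underscores preserved, branch lengths to 6 decimals).
    The underlying dendropy tree is exposed as ``.tree`` for callers that
    need traversal or MRCA machinery.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self.tree = tree
        names = self.leaf_names
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf names: {dupes}")
        if any(n is None or n == "" for n in names):
            raise ValueError("all leaves must be named")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
            raise ValueError(f"duplicate leaf names in Newick: {e}") from e
        return cls(tree)

    @classmethod
    def from_path(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- serialization ----------------------------------------------------

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
            real_value_format_specifier=".6f",
        )
        return s.strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- queries ----------------------------------------------------------

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def leaf(self, name: str) -> dendropy.Node:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == name:
                return lf
        raise KeyError(f"no leaf named {name!r}")

    def mrca(self, names: Iterable[str]) -> dendropy.Node:
        taxa = [self.leaf(n).taxon for n in names]
        if len(taxa) == 1:
            return self.leaf(taxa[0].label)
        node = self.tree.mrca(taxa=taxa)
        if node is None:
            raise ValueError("no common ancestor found (disconnected leaves?)")
        return node

    def find_clade(self, label: str) -> dendropy.Node:
        """Return the internal node carrying ``label`` (as written in Newick)."""
        for nd in self.tree.preorder_node_iter():
            if nd.label == label:
                return nd
            if nd.taxon is not None and nd.taxon.label == label and not nd.is_leaf():
                return nd
        raise KeyError(f"no internal node labeled {label!r}")

    def extract_clade(self, label: str) -> "PhyloTree":
        """New tree rooted at the internal node labeled ``label``."""
        node = self.find_clade(label)
        keep = [lf.taxon.label for lf in node.leaf_iter()]
        return self.extract_leaves(keep)

    def extract_leaves(self, names: Iterable[str]) -> "PhyloTree":
        names = set(names)
        sub = self.clone()
        sub.tree.retain_taxa_with_labels(list(names))
        return PhyloTree(sub.tree)

    def clone(self) -> "PhyloTree":
        return PhyloTree.from_newick(
            self.tree.as_string(schema="newick", unquoted_underscores=True)
        )

    def has_branch_lengths(self) -> bool:
        return all(
            e.length is not None
            for e in self.tree.preorder_edge_iter()
            if e.head_node is not self.tree.seed_node
        )

    def ensure_node_labels(self, prefix: str = "n") -> None:
        """Assign deterministic labels to unlabeled internal nodes (preorder)."""
        i = 0
        for nd in self.tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            if not nd.label:
                nd.label = f"{prefix}{i}"
            i += 1

    def node_label(self, node: dendropy.Node) -> Optional[str]:
        if node.is_leaf():
            return node.taxon.label
        return node.label

    def __len__(self) -> int:
        return len(self.leaf_names)
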