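"""Label candidate genes by their position in a reference tree, the
identity shortcut for jawed-fish TARLs, and phylogenetic-position naming.

Placement walks from a candidate leaf toward the root and assigns the
unique reference label of the first enclosing clade that contains any
reference leaf; a clade with several distinct reference labels falls back
to the patristically nearest reference inside it (an exact tie between
distinct labels yields UNKNOWN).  The result is invariant under child
reordering and uniform branch-length scaling.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Mapping, Optional

from famflux.align import percent_identity
from famflux.core import PipelineConfig, ProteinRecord
from famflux.trees import PhyloTree

LABEL_UNKNOWN = "UNKNOWN"


@dataclass
class LabeledTree:
    """A tree whose reference leaves carry labels; the rest are candidates."""

    tree: PhyloTree
    labels: Mapping[str, str]

    def __post_init__(self):
        leaves = set(self.tree.leaf_names)
        extra = set(self.labels) - leaves
        if extra:
            raise ValueError(f"labels for non-leaves: {sorted(extra)}")
        if not self.labels:
            raise ValueError("tree has no reference leaves")

    @property
    def candidates(self) -> list[str]:
        return [n for n in self.tree.leaf_names if n not in self.labels]


def _patristic_distances(tree: PhyloTree):
    """Leaf-pair distances; missing branch lengths count as unit edges."""
    work = tree.clone()
    for edge in work.tree.preorder_edge_iter():
        if edge.head_node is work.tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 1.0
    pdm = work.tree.phylogenetic_distance_matrix()

    def dist(a: str, b: str) -> float:
        ta = work.leaf(a).taxon
        tb = work.leaf(b).taxon
        return pdm.patristic_distance(ta, tb)

    return dist


def classify_by_placement(labeled: LabeledTree) -> dict[str, str]:
    """Assign a reference label to every candidate leaf.

    A candidate that itself carries a reference label is passed through
    unchanged.
    """
    tree = labeled.tree
    labels = labeled.labels
    dist = _patristic_distances(tree)
    out: dict[str, str] = {}
    for cand in tree.leaf_names:
        if cand in labels:
            out[cand] = labels[cand]
            continue
        node = tree.leaf(cand)
        assigned: Optional[str] = None
        anc = node.parent_node
        while anc is not None:
            refs = [
                lf.taxon.label
                for lf in anc.leaf_iter()
                if lf.taxon.label in labels and lf.taxon.label != cand
            ]
            if refs:
                ref_labels = {labels[r] for r in refs}
                if len(ref_labels) == 1:
                    assigned = ref_labels.pop()
                else:
                    best = sorted(refs, key=lambda r: (dist(cand, r), r))
                    d0 = dist(cand, best[0])
                    tied_labels = {
                        labels[r] for r in best if dist(cand, r) == d0
                    }
                    assigned = (
                        tied_labels.pop() if len(tied_labels) == 1 else LABEL_UNKNOWN
                    )
                break
            anc = anc.parent_node
        out[cand] = assigned if assigned is not None else LABEL_UNKNOWN
    return {c: out[c] for c in labeled.candidates} | {
        c: labels[c] for c in tree.leaf_names if c in labels
    }


def tarl_identity_shortcut(
    candidate: ProteinRecord,
    references: list[ProteinRecord],
    config: PipelineConfig | None = None,
) -> bool:
    """Screening pre-label for jawed-fish TARLs by sequence similarity.

    True iff the best identity against any reference reaches the floor
    (default 85%).  The final label always comes from placement; this is a
    cheap triage mirroring how strongly conserved the jawed-fish TARLs are.
    """
    if not references:
        raise ValueError("reference set must be non-empty")
    config = config or PipelineConfig()
    floor = config.tarl_identity_floor * 100.0
    return max(percent_identity(candidate, ref) for ref in references) >= floor


# -- naming by phylogenetic position --------------------------------------


def _letters(k: int) -> str:
    """0 -> 'a', 25 -> 'z', 26 -> 'aa', ..."""
    out = ""
    k += 1
    while k:
        k, rem = divmod(k - 1, 26)
        out = string.ascii_lowercase[rem] + out
    return out


def _root_path_length(node) -> float:
    total = 0.0
    while node.parent_node is not None:
        total += node.edge.length if node.edge.length is not None else 1.0
        node = node.parent_node
    return total


def _species_of(leaf_name: str, species_prefix: Mapping[str, str]) -> str:
    if leaf_name not in species_prefix:
        raise KeyError(f"no species prefix for gene {leaf_name!r}")
    return species_prefix[leaf_name]


def _auto_partition(tree: PhyloTree, species_prefix: Mapping[str, str]) -> list[list[str]]:
    """Subfamily delimitation by species overlap (experimental).

    Internal nodes whose children's species sets overlap are treated as
    ancient duplications separating subfamilies; a subfamily is a maximal
    clade free of such nodes (an ortholog group spanning species).  Supply
    an explicit partition instead when subfamilies are curated.
    """

    def species(leaf) -> str:
        return _species_of(leaf.taxon.label, species_prefix)

    def collect(node) -> tuple[list[list[str]], set, bool]:
        if node.is_leaf():
            return [[node.taxon.label]], {species(node)}, False
        child_results = [collect(c) for c in node.child_nodes()]
        sets = [r[1] for r in child_results]
        has_dup_below = any(r[2] for r in child_results)
        overlap = False
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    overlap = True
        merged = set().union(*sets)
        if overlap or has_dup_below:
            groups: list[list[str]] = []
            for r in child_results:
                groups.extend(r[0])
            return groups, merged, True
        return [[lf.taxon.label for lf in node.leaf_iter()]], merged, False

    groups, _, _ = collect(tree.tree.seed_node)
    return groups


def assign_names(
    family_tree: PhyloTree,
    species_prefix: Mapping[str, str],
    family: str,
    partition: Optional[list[list[str]]] = None,
) -> dict[str, str]:
    """Name genes "<SpeciesPrefix>-<family><subfamily><letter>".

    Subfamilies are numbered 1..k from least-derived (shortest root path of
    their ancestral node) to most-derived; genes within a subfamily are
    lettered a, b, c, ... in order of divergence, again least-derived
    first.  Deterministic: ties break on the lexicographically smallest
    leaf.  Adding a new most-derived gene extends the lettering without
    renaming existing genes.
    """
    leaves = family_tree.leaf_names
    if len(leaves) == 1:
        return {leaves[0]: f"{_species_of(leaves[0], species_prefix)}-{family}1a"}
    if partition is None:
        partition = _auto_partition(family_tree, species_prefix)

    covered = {lf for grp in partition for lf in grp}
    if covered != set(leaves):
        raise ValueError("partition must cover exactly the tree's leaves")

    def group_key(group: list[str]):
        mrca = family_tree.mrca(group) if len(group) > 1 else family_tree.leaf(group[0])
        return (_root_path_length(mrca), min(group))

    ordered_groups = sorted(partition, key=group_key)
    names: dict[str, str] = {}
    for num, group in enumerate(ordered_groups, start=1):
        ordered = sorted(
            group, key=lambda lf: (_root_path_length(family_tree.leaf(lf)), lf)
        )
        for k, leaf_name in enumerate(ordered):
            prefix = _species_of(leaf_name, species_prefix)
            names[leaf_name] = f"{prefix}-{family}{num}{_letters(k)}"
    return names
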