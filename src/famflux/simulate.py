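"""Gene-family evolution simulator with known ground truth.

A linear birth-death process runs along every branch of a rooted species
tree: each gene lineage independently duplicates at rate ``lambda_dup`` and
is lost at rate ``mu_loss`` per unit branch length, starting from ``n0``
genes at the root (a single-origin family, so the Dollo single-gain
assumption holds on simulated data by construction).  The simulator also
evolves protein sequences along the resulting gene genealogy, carrying a
class-specific fingerprint motif held invariant, and can embed a coding
sequence into a random genomic fragment for ORF-completion round-trips.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from famflux.core import CountMatrix, ProteinRecord
from famflux.motif import (
    CLASS_CRITICAL,
    CRITICAL_OFFSETS,
    CTERM_CAP,
    MOTIF_OFFSET_FROM_END,
    MOTIF_SCAFFOLD,
    TM7_BLOCK,
    TM7_OFFSET_FROM_END,
)
from famflux.trees import PhyloTree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODONS = set(standard_dna_table.stop_codons)

# lexicographically smallest codon per amino acid: an arbitrary but fixed
# back-translation table (codon-usage realism is irrelevant to the logic
# under test)
BACKTRANSLATION = {
    aa: min(c for c, a in standard_dna_table.forward_table.items() if a == aa)
    for aa in AMINO_ACIDS
}


@dataclass
class SimParams:
    """Birth-death and sequence-evolution parameters.

    Rates are per gene and per unit branch length; ``subst_rate`` is
    substitutions per site per unit branch length under a uniform
    replacement model (the replacement residue is drawn uniformly from all
    20 amino acids, so a fraction 1/20 of events is silent).
    """

    lambda_dup: float = 0.0
    mu_loss: float = 0.0
    n0: int = 1
    seq_len_aa: int = 120
    subst_rate: float = 0.05
    seed: int = 0
    family_tag: str = "fam1"

    def __post_init__(self):
        if self.lambda_dup < 0 or self.mu_loss < 0:
            raise ValueError("rates must be non-negative")
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.seq_len_aa < TM7_OFFSET_FROM_END + 1:
            raise ValueError(
                f"seq_len_aa must be >= {TM7_OFFSET_FROM_END + 1} "
                "to hold the TM7 block and fingerprint motif"
            )
        if self.subst_rate < 0:
            raise ValueError("subst_rate must be non-negative")


@dataclass(frozen=True)
class SimEvent:
    """One recorded event: a duplication or loss on a species-tree branch."""

    kind: str  # "duplication" | "loss"
    branch: str  # label of the child node of the species-tree edge
    time: float  # time from the start of the branch
    lineage: int


class _GeneNode:
    __slots__ = ("uid", "children", "length", "leaf_name")

    def __init__(self, uid: int):
        self.uid = uid
        self.children: list[_GeneNode] = []
        self.length = 0.0
        self.leaf_name: Optional[str] = None


@dataclass
class SimTruth:
    """Ground truth of one simulated family."""

    events: list[SimEvent]
    genealogy: Optional[PhyloTree]  # None if the family went extinct
    counts: CountMatrix
    species_tree: PhyloTree  # labeled clone used for branch ids
    params: SimParams

    @property
    def n_losses(self) -> int:
        return sum(1 for e in self.events if e.kind == "loss")

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events if e.kind == "duplication")


def simulate_family(species_tree: PhyloTree, params: SimParams) -> SimTruth:
    """Run the birth-death process over the species tree.

    Returns event log, surviving-gene genealogy and per-species counts
    (a one-column count matrix for ``params.family_tag``).
    """
    tree = species_tree.clone()
    tree.ensure_node_labels()
    for edge in tree.tree.preorder_edge_iter():
        if edge.head_node is tree.tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("species tree must have branch lengths")

    rng = np.random.default_rng(params.seed)
    lam, mu = params.lambda_dup, params.mu_loss
    rate = lam + mu
    events: list[SimEvent] = []
    counts: dict[str, int] = {}
    uid_counter = [0]

    def new_node() -> _GeneNode:
        node = _GeneNode(uid_counter[0])
        uid_counter[0] += 1
        return node

    def evolve(g: _GeneNode, branch: str, remaining: float, elapsed: float) -> list[_GeneNode]:
        while True:
            if rate == 0.0:
                g.length += remaining
                return [g]
            wait = rng.exponential(1.0 / rate)
            if wait >= remaining:
                g.length += remaining
                return [g]
            remaining -= wait
            elapsed += wait
            g.length += wait
            if rng.random() < (lam / rate if rate > 0 else 0.0):
                events.append(SimEvent("duplication", branch, elapsed, g.uid))
                left, right = new_node(), new_node()
                g.children = [left, right]
                out = evolve(left, branch, remaining, elapsed)
                out += evolve(right, branch, remaining, elapsed)
                return out
            events.append(SimEvent("loss", branch, elapsed, g.uid))
            return []

    def descend(species_node, genes: list[_GeneNode]) -> None:
        if species_node.is_leaf():
            leaf = species_node.taxon.label
            counts[leaf] = len(genes)
            for k, g in enumerate(genes):
                g.leaf_name = f"{leaf}_g{k}"
            return
        for child in species_node.child_nodes():
            branch = tree.node_label(child)
            survivors_for_child: list[_GeneNode] = []
            for g in genes:
                seg = new_node()
                g.children.append(seg)
                survivors_for_child += evolve(seg, branch, child.edge.length, 0.0)
            descend(child, survivors_for_child)

    root_genes = [new_node() for _ in range(params.n0)]
    gene_root = new_node()
    gene_root.children = root_genes
    descend(tree.tree.seed_node, root_genes)

    for leaf in tree.leaf_names:
        counts.setdefault(leaf, 0)
    matrix = CountMatrix(
        pd.DataFrame({params.family_tag: pd.Series(counts)}).loc[tree.leaf_names]
    )
    genealogy = _genealogy_tree(gene_root)
    return SimTruth(events, genealogy, matrix, tree, params)


def _genealogy_newick(node: _GeneNode, extra_len: float) -> Optional[str]:
    """Serialize surviving lineages, suppressing unifurcations."""
    length = node.length + extra_len
    if node.leaf_name is not None:
        return f"{node.leaf_name}:{length:.6f}"
    alive = []
    for child in node.children:
        s = _genealogy_newick(child, 0.0)
        if s is not None:
            alive.append((child, s))
    if not alive:
        return None
    if len(alive) == 1:
        # merge the unifurcation into its single surviving child
        return _genealogy_newick(alive[0][0], length)
    inner = ",".join(s for _, s in alive)
    return f"({inner}):{length:.6f}"


def _genealogy_tree(gene_root: _GeneNode) -> Optional[PhyloTree]:
    s = _genealogy_newick(gene_root, 0.0)
    if s is None:
        return None
    cut = s.rfind(":")
    if cut > s.rfind(")"):  # drop the root branch length
        s = s[:cut]
    if not s.startswith("("):  # single surviving gene
        s = f"({s})"
    return PhyloTree.from_newick(s + ";")


def replay_counts(truth: SimTruth) -> CountMatrix:
    """Recompute leaf counts from the event log alone (replay invariant)."""
    deltas: dict[str, int] = {}
    for e in truth.events:
        deltas[e.branch] = deltas.get(e.branch, 0) + (1 if e.kind == "duplication" else -1)
    tree = truth.species_tree
    entering = {tree.node_label(tree.tree.seed_node): truth.params.n0}
    counts: dict[str, int] = {}
    for node in tree.tree.preorder_node_iter():
        label = tree.node_label(node)
        if node is tree.tree.seed_node:
            pass
        else:
            parent_label = tree.node_label(node.parent_node)
            entering[label] = entering[parent_label] + deltas.get(label, 0)
        if node.is_leaf():
            counts[label] = entering[label]
    matrix = pd.DataFrame({truth.params.family_tag: pd.Series(counts)}).loc[tree.leaf_names]
    return CountMatrix(matrix)


# -- sequence evolution ---------------------------------------------------


def _root_sequence(rng: np.random.Generator, length: int, motif_class: str) -> list[str]:
    seq = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)]
    seq[0] = "M"  # complete ORFs start with Met; kept invariant
    for k, res in enumerate(TM7_BLOCK):
        seq[length - TM7_OFFSET_FROM_END + k] = res
    for k, res in enumerate(CTERM_CAP):
        seq[length - len(CTERM_CAP) + k] = res
    offset = length - MOTIF_OFFSET_FROM_END
    c1, c2 = CLASS_CRITICAL[motif_class]
    for k, res in enumerate(MOTIF_SCAFFOLD):
        seq[offset + k] = res
    seq[offset + CRITICAL_OFFSETS[0]] = c1
    seq[offset + CRITICAL_OFFSETS[1]] = c2
    return seq


def simulate_sequences(
    truth: SimTruth, params: SimParams, motif_class: str = "TAAR"
) -> list[ProteinRecord]:
    """Evolve protein sequences along the genealogy of a simulated family.

    The fingerprint motif window (scaffold plus the two critical residues
    of ``motif_class``) and the initial Met are held invariant; every other
    site substitutes at ``subst_rate`` with uniform replacement over the 20
    amino acids.
    """
    if motif_class not in CLASS_CRITICAL:
        raise ValueError(f"unknown motif class {motif_class!r}")
    if truth.genealogy is None:
        raise ValueError("family went extinct; no sequences to simulate")
    length = params.seq_len_aa
    offset = length - MOTIF_OFFSET_FROM_END
    invariant = (
        {0}
        | {offset + k for k in range(len(MOTIF_SCAFFOLD))}
        | {length - TM7_OFFSET_FROM_END + k for k in range(len(TM7_BLOCK))}
        | {length - len(CTERM_CAP) + k for k in range(len(CTERM_CAP))}
    )
    variable = np.array([i for i in range(length) if i not in invariant])

    rng = np.random.default_rng([params.seed, 7])
    root_seq = np.array(_root_sequence(rng, length, motif_class))
    records: list[ProteinRecord] = []

    def walk(node, seq: np.ndarray) -> None:
        if node.edge.length:
            p_event = 1.0 - math.exp(-params.subst_rate * node.edge.length)
            hit = variable[rng.random(variable.size) < p_event]
            if hit.size:
                seq = seq.copy()
                seq[hit] = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=hit.size)]
        if node.is_leaf():
            name = node.taxon.label
            species = name.rsplit("_g", 1)[0]
            records.append(
                ProteinRecord(
                    id=name,
                    species=species,
                    sequence="".join(seq),
                    family_label=motif_class,
                )
            )
            return
        for child in node.child_nodes():
            walk(child, seq)

    walk(truth.genealogy.tree.seed_node, root_seq)
    return records


# -- genomic embedding ----------------------------------------------------


def _flank(rng: np.random.Generator, n_nt: int) -> str:
    """Random flank, codon-aligned to the CDS frame, free of in-frame ATG
    and stop codons (keeps the farthest-ATG extension rule deterministic)."""
    allowed = sorted(
        c
        for c in standard_dna_table.forward_table
        if c != "ATG" and c not in STOP_CODONS
    )
    n_codons = (n_nt + 2) // 3
    codons = [allowed[i] for i in rng.integers(0, len(allowed), size=n_codons)]
    s = "".join(codons)
    return s[len(s) - n_nt :] if n_nt else ""


def embed_in_genome(
    record: ProteinRecord, flank_nt: int, seed: int, strand: str = "+"
) -> tuple[str, tuple[int, int]]:
    """Back-translate a protein and embed its CDS in random genomic flanks.

    Returns the genomic fragment and a deliberately truncated hit interval
    strictly inside the CDS (forward-strand coordinates; for ``strand='-'``
    the fragment is reverse-complemented and the interval remapped).  The
    protein must start with Met and be free of 'X'/'*' so the CDS is exact.
    """
    if flank_nt < 0:
        raise ValueError("flank_nt must be >= 0")
    seq = record.sequence
    if seq[0] != "M":
        raise ValueError("embedded protein must start with Met")
    if "X" in seq or "*" in seq:
        raise ValueError("cannot back-translate 'X' or internal stops")
    rng = np.random.default_rng(seed)
    cds = "".join(BACKTRANSLATION[aa] for aa in seq) + "TAA"
    up = _flank(rng, flank_nt)
    down = _flank(rng, flank_nt)
    forward = up + cds + down

    n_aa = len(seq)
    if n_aa < 4:
        raise ValueError("protein too short to truncate an interior interval")
    slack = max(1, n_aa // 4)
    a = 1 + int(rng.integers(0, slack))
    b = n_aa - int(rng.integers(0, slack))
    if b <= a:
        b = a + 1
    start = flank_nt + 3 * a
    end = flank_nt + 3 * b

    if strand == "+":
        return forward, (start, end)
    if strand == "-":
        rc = str(Seq(forward).reverse_complement())
        return rc, (len(forward) - end, len(forward) - start)
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")
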