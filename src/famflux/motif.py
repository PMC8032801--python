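"""Alignment post-processing, the fingerprint-motif classifier, and a
neighbor-joining builder used as test plumbing.

The fingerprint motif is a short conserved residue pattern adjacent to
transmembrane region 7 whose two critical positions discriminate the
receptor classes: (Y, W) marks a TAAR, (N, S) a jawed-fish TARL, and
(N, anything else) a non-TAAR aminergic-type receptor.  The scaffold
positions around the critical pair are conserved across all classes.

The default profile ships as a data file with a synthetic anchor (the
published motif is shown graphically only, so machine-readable columns are
curated here); the simulator writes the same motif layout, which is what
makes perfect class separation on simulated data a meaningful check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Optional

import importlib.resources
import numpy as np

from famflux.align import global_align, percent_identity
from famflux.core import ProteinRecord
from famflux.trees import PhyloTree

# shared motif layout: scaffold residues, '?' at the two critical positions
MOTIF_SCAFFOLD = "NSAVNPLI?GAL?F"
CRITICAL_OFFSETS = (8, 12)
MOTIF_OFFSET_FROM_END = 20  # motif occupies [L-20, L-6) of a length-L sequence
# transmembrane-region-7 block conserved in ALL receptor classes, directly
# N-terminal of the motif; it anchors the alignment to the profile even when
# the rest of the sequence has diverged beyond recognition
TM7_BLOCK = "FVLWLPYFIVAT"
TM7_OFFSET_FROM_END = 34  # block occupies [L-34, L-22)
# short conserved cap closing the C-terminus in all classes; pins the
# alignment column map on both sides of the motif
CTERM_CAP = "ERAKSF"  # occupies [L-6, L)
CLASS_CRITICAL = {
    "TAAR": ("Y", "W"),
    "TARL_JAWED": ("N", "S"),
    "NONTAAR": ("N", "G"),
}

LABEL_TAAR = "TAAR"
LABEL_TARL_JAWED = "TARL_JAWED"
LABEL_NON_TAAR = "NON_TAAR"
LABEL_UNKNOWN = "UNKNOWN"
LABEL_UNALIGNABLE = "UNALIGNABLE"


@dataclass
class Alignment:
    """An aligned set of protein records (gap character '-')."""

    records: list[ProteinRecord]

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment must have at least one row")
        width = len(self.records[0].sequence)
        for rec in self.records:
            if len(rec.sequence) != width:
                raise ValueError(
                    f"row {rec.id!r} has length {len(rec.sequence)}, expected {width}"
                )

    @property
    def width(self) -> int:
        return len(self.records[0].sequence)

    def __len__(self) -> int:
        return len(self.records)

    def column(self, j: int) -> str:
        return "".join(rec.sequence[j] for rec in self.records)


def strip_gap_columns(aln: Alignment, tolerance: float) -> tuple[Alignment, list[int]]:
    """Remove columns whose gap fraction is >= tolerance (boundary inclusive).

    Returns the stripped alignment and the removed column indices, so
    coordinates can be mapped back to the original alignment.
    """
    if not (0 < tolerance <= 1):
        raise ValueError("tolerance must be in (0, 1]")
    n = len(aln)
    removed = [
        j for j in range(aln.width) if aln.column(j).count("-") / n >= tolerance
    ]
    removed_set = set(removed)
    kept_records = []
    for rec in aln.records:
        seq = "".join(c for j, c in enumerate(rec.sequence) if j not in removed_set)
        kept_records.append(
            ProteinRecord(rec.id, rec.species, seq or "-", rec.family_label)
        )
    return Alignment(kept_records), removed


@dataclass
class FingerprintProfile:
    """Motif description: anchor sequence, motif columns, class rules.

    ``rules`` map ordered two-character patterns at the critical columns to
    labels; '?' matches any residue not captured by an earlier rule.  Rules
    are evaluated in order, so disjointness is by construction.
    """

    anchor: str
    motif_columns: list[int]
    critical_columns: tuple[int, int]
    rules: list[tuple[str, str, str]]  # (pattern_c1, pattern_c2, label)
    # coarse screen against garbage input: a candidate must reach this
    # fraction of the anchor self-score to be classified at all
    score_floor_fraction: float = 0.03
    _self_score: float = field(default=0.0, repr=False)

    def __post_init__(self):
        if not set(self.critical_columns) <= set(self.motif_columns):
            raise ValueError("critical columns must be motif columns")
        self._self_score = global_align(self.anchor, self.anchor).score

    @classmethod
    def from_tsv(cls, path) -> "FingerprintProfile":
        with open(path) as fh:
            return cls._parse(fh.read())

    @classmethod
    def _parse(cls, text: str) -> "FingerprintProfile":
        anchor = None
        motif: list[int] = []
        critical: dict[int, int] = {}
        rules: list[tuple[str, str, str]] = []
        for line in StringIO(text):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            tag = parts[0]
            if tag == "anchor":
                anchor = parts[1]
            elif tag == "motif":
                motif.append(int(parts[1]))
            elif tag == "critical":
                critical[int(parts[2])] = int(parts[1])
            elif tag == "rule":
                pat, label = parts[1], parts[2]
                rules.append((pat[0], pat[1], label))
            else:
                raise ValueError(f"unknown profile line tag {tag!r}")
        if anchor is None or len(critical) != 2:
            raise ValueError("profile needs an anchor and exactly two critical columns")
        crit = (critical[1], critical[2])
        return cls(anchor=anchor, motif_columns=sorted(set(motif) | set(crit)),
                   critical_columns=crit, rules=rules)

    @classmethod
    def default(cls) -> "FingerprintProfile":
        """The packaged profile (synthetic anchor, standard class rules)."""
        ref = importlib.resources.files("famflux").joinpath(
            "data", "taar_fingerprint.profile.tsv"
        )
        return cls._parse(ref.read_text())


@dataclass
class MotifReport:
    """Classification outcome plus residues observed at all motif columns."""

    label: str
    residues: dict[int, Optional[str]]
    score: float


def fingerprint_classify(
    record: ProteinRecord, profile: FingerprintProfile
) -> MotifReport:
    """Label a sequence by the residues at the profile's critical columns.

    The record is globally aligned to the anchor; residues are read through
    the resulting column map.  An alignment scoring below the profile floor
    yields the UNALIGNABLE outcome rather than an exception.
    """
    aln = global_align(profile.anchor, record.sequence)
    floor = profile.score_floor_fraction * profile._self_score
    residues: dict[int, Optional[str]] = {}
    anchor_pos = -1
    col_to_res: dict[int, Optional[str]] = {}
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-":
            anchor_pos += 1
            col_to_res[anchor_pos] = cb if cb != "-" else None
    for col in profile.motif_columns:
        residues[col] = col_to_res.get(col)
    if aln.score < floor:
        return MotifReport(LABEL_UNALIGNABLE, residues, aln.score)
    c1 = residues.get(profile.critical_columns[0])
    c2 = residues.get(profile.critical_columns[1])
    label = LABEL_UNKNOWN
    if c1 is not None and c2 is not None:
        for p1, p2, rule_label in profile.rules:
            if (p1 == "?" or p1 == c1) and (p2 == "?" or p2 == c2):
                label = rule_label
                break
    return MotifReport(label, residues, aln.score)


def nj_tree(records: list[ProteinRecord]) -> PhyloTree:
    """Neighbor-joining tree on distance 1 - identity/100.

    Test plumbing: stands in for external ML tree building so placement
    tests run without third-party tools.  Leaf order in the distance matrix
    is lexicographic, which fixes the agglomeration tie-break.
    """
    if len(records) < 3:
        raise ValueError("neighbor joining needs at least 3 records")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    recs = sorted(records, key=lambda r: r.id)
    ids = [r.id for r in recs]
    n = len(recs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - percent_identity(recs[i], recs[j]) / 100.0
            mat[i, j] = mat[j, i] = d
    tree = nj(DistanceMatrix(mat, ids))
    buf = StringIO()
    tree.write(buf, format="newick")
    return PhyloTree.from_newick(buf.getvalue())
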