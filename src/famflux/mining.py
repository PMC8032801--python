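"""Candidate gene identification: stopping-rule scan, ORF completion,
minimum-length filter.

The stopping rule mirrors the survey protocol for ranked homology-hit
lists: scanning stops before the first hit whose e-value exceeds the floor
(1e-10 by default; a hit at exactly the floor is retained), or immediately
after a run of 10 consecutive off-target hits, whichever fires first.
Hits flagged UNKNOWN are retained as candidates (they are validated
downstream by phylogeny) but break off-target runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from famflux.core import ClassFlag, HitRow, HitTable, PipelineConfig, ProteinRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class RetainedCandidate:
    """A retained hit row, optionally with its completed protein."""

    hit: HitRow
    protein: Optional[ProteinRecord] = None
    incompletion: Optional[str] = None  # NO_START | NO_STOP


@dataclass
class CandidateSet:
    """Output of the stopping-rule scan over a ranked hit list."""

    retained: list[RetainedCandidate] = field(default_factory=list)
    stop_reason: str = "EXHAUSTED"  # EVALUE_FLOOR | CONSECUTIVE_OFFTARGET | EXHAUSTED
    stop_rank: int = 0


def apply_stopping_rule(hits: HitTable, config: PipelineConfig) -> CandidateSet:
    """Scan a ranked hit table and stop per the e-value / run-length rule."""
    prev = None
    for row in hits:
        if prev is not None and row.evalue < prev:
            raise ValueError("hit table not sorted by ascending e-value")
        prev = row.evalue

    retained: list[RetainedCandidate] = []
    run = 0
    stop_reason = "EXHAUSTED"
    stop_rank = len(hits)
    for rank, row in enumerate(hits):
        if row.evalue > config.evalue_stop:
            stop_reason = "EVALUE_FLOOR"
            stop_rank = rank
            break
        if row.class_flag == ClassFlag.OTHER:
            run += 1
            if run >= config.consecutive_offtarget_stop:
                stop_reason = "CONSECUTIVE_OFFTARGET"
                stop_rank = rank + 1
                break
        else:
            run = 0
            retained.append(RetainedCandidate(hit=row))
    return CandidateSet(retained=retained, stop_reason=stop_reason, stop_rank=stop_rank)


@dataclass
class OrfResult:
    """Completed ORF or the reason completion failed."""

    protein: Optional[ProteinRecord]
    reason: Optional[str]  # NO_START | NO_STOP | None
    cds_start: int = -1  # working-strand coordinates of the completed CDS
    cds_end: int = -1  # end of the coding region, stop codon excluded
    start_rule: str = "farthest_atg"

    @property
    def ok(self) -> bool:
        return self.protein is not None


def complete_orf(
    genomic: str,
    interval: tuple[int, int],
    strand: str,
    config: PipelineConfig,
    record_id: str = "orf",
) -> OrfResult:
    """Extend a hit interval to the full coding region and translate it.

    Searches upstream (up to ``orf_extension_nt``) for the farthest in-frame
    ATG not preceded, in frame and inside the window, by a stop codon; and
    downstream for the first in-frame stop.  The reading frame is taken from
    the interval start.  Reverse-strand intervals are given in forward
    coordinates and processed on the reverse complement.
    """
    genomic = genomic.upper()
    start, end = interval
    if not (0 <= start < end <= len(genomic)):
        raise ValueError(f"interval [{start}, {end}) out of sequence bounds")
    if strand == "-":
        seq = str(Seq(genomic).reverse_complement())
        start, end = len(genomic) - end, len(genomic) - start
    elif strand == "+":
        seq = genomic
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    window = config.orf_extension_nt
    # upstream: farthest in-frame ATG before any in-frame stop
    atg = None
    p = start
    lo = max(0, start - window)
    while p >= lo:
        codon = seq[p : p + 3]
        if codon in STOP_CODONS:
            break
        if codon == "ATG":
            atg = p
        p -= 3
    if atg is None:
        return OrfResult(None, "NO_START")

    # downstream: first in-frame stop within the window past the interval end
    q = start
    hi = min(len(seq), end + window)
    stop_at = None
    while q + 3 <= hi:
        if seq[q : q + 3] in STOP_CODONS and q >= atg:
            stop_at = q
            break
        q += 3
    if stop_at is None:
        return OrfResult(None, "NO_STOP")

    cds = seq[atg:stop_at]
    protein = str(Seq(cds).translate())
    record = ProteinRecord(id=record_id, sequence=protein)
    return OrfResult(record, None, cds_start=atg, cds_end=stop_at)


def length_filter(
    records: list[ProteinRecord], config: PipelineConfig
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition records into (kept, rejected) at the minimum length.

    The threshold is inclusive (a 200-aa candidate passes the default 200);
    stop symbols do not count toward the length.
    """
    kept = [r for r in records if len(r) >= config.min_len_aa]
    rejected = [r for r in records if len(r) < config.min_len_aa]
    return kept, rejected
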