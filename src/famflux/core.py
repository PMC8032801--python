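"""Shared domain types: protein records, hit tables, count matrices, config.

Conventions used throughout the package:

* Genomic coordinates are 0-based, half-open.  Intervals on the reverse
  strand are stored on the forward strand together with a strand flag, so
  ORF-extension arithmetic never has to branch on strand until the sequence
  is actually extracted.
* A protein sequence is pseudogenised iff it contains an internal stop
  ('*'); a terminal stop is bookkeeping noise and is stripped on record
  construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*", "-"}


class ClassFlag:
    """Class annotation of a homology hit row."""

    TARGET_CLASS = "TARGET_CLASS"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"

    ALL = frozenset({TARGET_CLASS, OTHER, UNKNOWN})


@dataclass
class ProteinRecord:
    """One amino-acid sequence with species tag and optional family label.

    ``pseudogene`` is derived from the sequence on construction: true iff
    the sequence carries an internal '*'.  A single terminal '*' is
    stripped.  Pass ``truncated=True`` to flag a sequence known to be
    incomplete from external evidence.
    """

    id: str
    species: str
    sequence: str
    family_label: Optional[str] = None
    pseudogene: bool = field(default=False)

    def __init__(
        self,
        id: str,
        species: str = "",
        sequence: str = "",
        family_label: Optional[str] = None,
        truncated: bool = False,
    ):
        if not id:
            raise ValueError("protein record id must be non-empty")
        seq = sequence.upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"record {id!r}: sequence must be non-empty")
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValueError(f"record {id!r}: invalid residues {sorted(bad)}")
        self.id = id
        self.species = species
        self.sequence = seq
        self.family_label = family_label
        self.pseudogene = ("*" in seq) or truncated

    def __len__(self) -> int:
        """Residue count; stop symbols and alignment gaps excluded."""
        return len(self.sequence.replace("*", "").replace("-", ""))


def check_unique_ids(records: Iterable[ProteinRecord]) -> None:
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)


@dataclass(frozen=True)
class HitRow:
    """One homology hit: genomic interval plus e-value and class flag."""

    query: str
    subject: str
    start: int
    end: int
    strand: str
    evalue: float
    class_flag: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"hit {self.query}->{self.subject}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (self.evalue > 0 or self.evalue == 0.0):
            raise ValueError("e-value must be >= 0")
        if self.evalue < 0:
            raise ValueError("e-value must be positive")
        if self.class_flag not in ClassFlag.ALL:
            raise ValueError(f"unknown class flag {self.class_flag!r}")


class HitTable:
    """Ordered homology hits, sorted by ascending e-value.

    The table is the raw material of candidate mining; it is validated on
    construction and never silently re-sorted (an unsorted input is a
    caller error the stopping rule must not paper over).
    """

    COLUMNS = ["query", "subject", "start", "end", "strand", "evalue", "class_flag"]

    def __init__(self, rows: Iterable[HitRow]):
        self.rows = list(rows)
        for prev, cur in zip(self.rows, self.rows[1:]):
            if cur.evalue < prev.evalue:
                raise ValueError(
                    "hit table must be sorted by ascending e-value "
                    f"({prev.evalue:g} followed by {cur.evalue:g})"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __getitem__(self, i):
        return self.rows[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows], columns=self.COLUMNS)


class CountMatrix:
    """Species x family non-negative gene counts, backed by a DataFrame."""

    def __init__(self, counts: pd.DataFrame):
        df = counts.copy()
        if df.index.has_duplicates:
            raise ValueError("duplicate species tags in count matrix")
        if df.columns.has_duplicates:
            raise ValueError("duplicate family tags in count matrix")
        for sp in df.index:
            for fam in df.columns:
                v = df.loc[sp, fam]
                if pd.isna(v):
                    raise ValueError(f"missing count for species {sp!r}, family {fam!r}")
                if isinstance(v, float) and not float(v).is_integer():
                    raise ValueError(
                        f"non-integer count {v!r} for species {sp!r}, family {fam!r}"
                    )
                if int(v) < 0:
                    raise ValueError(
                        f"negative count {v!r} for species {sp!r}, family {fam!r}"
                    )
        self.counts = df.astype(int)

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    def count(self, species: str, family: str) -> int:
        return int(self.counts.loc[species, family])

    def presence(self, family: str) -> dict[str, bool]:
        """Presence/absence of a family, thresholded at count >= 1."""
        col = self.counts[family]
        return {sp: bool(col[sp] >= 1) for sp in self.counts.index}

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)


@dataclass
class PipelineConfig:
    """Numeric thresholds of the mining/classification pipeline.

    Defaults encode the survey protocol: candidates of at least 200 aa,
    hit-list scan stopped at e-value 1e-10 or after 10 consecutive
    off-target hits, ORF extension up to 2 kb each direction, gap-column
    stripping at the 90% tolerance level, and an 85% identity floor for
    the jawed-fish TARL similarity shortcut.
    """

    min_len_aa: int = 200
    evalue_stop: float = 1e-10
    consecutive_offtarget_stop: int = 10
    orf_extension_nt: int = 2000
    gap_tolerance: float = 0.90
    tarl_identity_floor: float = 0.85
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.gap_tolerance <= 1):
            raise ValueError("gap_tolerance must be in (0, 1]")
        if not (0 < self.tarl_identity_floor <= 1):
            raise ValueError("tarl_identity_floor must be in (0, 1]")
        for name in ("min_len_aa", "consecutive_offtarget_stop", "orf_extension_nt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.evalue_stop <= 0:
            raise ValueError("evalue_stop must be positive")
        if math.isnan(self.evalue_stop):
            raise ValueError("evalue_stop must be a number")
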