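"""Readers and writers for the text formats the pipeline touches.

FASTA headers follow ``id|species`` (bare ``id`` is accepted, species then
empty).  All tabular formats are UTF-8, tab-separated; lines starting with
'#' are comments.  Packaged fixtures (the published repertoire count table
and the hand-encoded species-tree topology) load through
:func:`load_table1` / :func:`load_species_tree`.
"""

from __future__ import annotations

import importlib.resources
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from famflux.core import ClassFlag, CountMatrix, HitRow, HitTable, ProteinRecord, check_unique_ids
from famflux.trees import PhyloTree


# -- FASTA ----------------------------------------------------------------


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein FASTA into records; empty file yields an empty list.

    A header with more than one '|' is rejected as malformed; the record
    id must be non-empty.
    """
    records = []
    for i, entry in enumerate(SeqIO.parse(str(path), "fasta")):
        header = entry.description.split()[0] if entry.description else entry.id
        parts = header.split("|")
        if len(parts) == 1:
            rec_id, species = parts[0], ""
        elif len(parts) == 2:
            rec_id, species = parts
        else:
            raise ValueError(f"malformed FASTA header at entry {i + 1}: {header!r}")
        if not rec_id:
            raise ValueError(f"empty id in FASTA header at entry {i + 1}: {header!r}")
        records.append(ProteinRecord(id=rec_id, species=species, sequence=str(entry.seq)))
    check_unique_ids(records)
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f"{rec.id}|{rec.species}" if rec.species else rec.id
            fh.write(f">{header}\n{rec.sequence}\n")


# -- Newick ---------------------------------------------------------------


def read_newick(path) -> PhyloTree:
    return PhyloTree.from_path(path)


def write_newick(tree: PhyloTree, path) -> None:
    tree.write(path)


# -- count matrices -------------------------------------------------------


def read_count_matrix(path) -> CountMatrix:
    """Read a species x family count TSV (header = family tags)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return CountMatrix(df)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="species")


# -- hit tables -----------------------------------------------------------


def read_hit_table(path) -> HitTable:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"query": str, "subject": str},
        float_precision="round_trip",
    )
    missing = set(HitTable.COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    rows = [
        HitRow(
            query=r.query,
            subject=r.subject,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            evalue=float(r.evalue),
            class_flag=r.class_flag,
        )
        for r in df.itertuples()
    ]
    return HitTable(rows)


def write_hit_table(table: HitTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# -- packaged fixtures ----------------------------------------------------


def _data_path(name: str):
    return importlib.resources.files("famflux").joinpath("data", name)


def load_table1() -> CountMatrix:
    """The published class-II taar / tarl repertoire counts (76 species).

    Transcribed as printed, including count entries that disagree with the
    original running text (e.g. channel catfish taar13).
    """
    with importlib.resources.as_file(_data_path("table1.tsv")) as p:
        return read_count_matrix(p)


def load_species_tree() -> PhyloTree:
    """Hand-encoded species-tree topology for the count-table species.

    Topology only (no branch lengths), following the published ordinal-level
    fish phylogeny the survey's gain/loss figure is drawn on.  Major clades
    (Percomorphaceae, Ovalentaria, Eupercaria, ...) are labeled on internal
    nodes so subtrees can be extracted by name.
    """
    with importlib.resources.as_file(_data_path("species_tree_table1.nwk")) as p:
        return read_newick(p)


__all__ = [
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_count_matrix",
    "write_count_matrix",
    "read_hit_table",
    "write_hit_table",
    "load_table1",
    "load_species_tree",
    "ClassFlag",
]
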