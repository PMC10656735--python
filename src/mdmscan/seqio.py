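"""Readers and writers for the external formats the pipeline touches.

FASTA goes through Biopython; tabular formats go through pandas.  The BIOM
reader supports the minimal dense JSON dialect (format 1.0) only, which is
all the OTU-table stage needs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes (DNA, with ambiguity codes).
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")

#: Sentinel for a rank that could not be resolved.
UNKNOWN = "UNKNOWN"

#: The seven canonical ranks, highest first.
RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus", "species")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence with a unique id — the atom of every stage."""

    id: str
    seq: str
    desc: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id must be non-empty without whitespace, got {self.id!r}")
        if not self.seq:
            raise FormatError(f"empty sequence for record {self.id!r}")
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - IUPAC_DNA
        if bad:
            raise FormatError(f"record {self.id!r} contains non-IUPAC characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Lineage:
    """Ordered seven-rank taxonomy; UNKNOWN is prefix-closed downward."""

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != 7:
            raise FormatError(f"lineage needs exactly 7 ranks, got {len(self.ranks)}")
        seen_unknown = False
        for r in self.ranks:
            if r == UNKNOWN:
                seen_unknown = True
            elif seen_unknown:
                raise FormatError(f"lineage not prefix-closed: {self.ranks}")

    @classmethod
    def from_string(cls, text: str, sep: str = ";") -> "Lineage":
        """Parse ``Bacteria;Nitrospirota;...``; repairs prefix-closure by truncation."""
        parts = [p.strip() for p in text.split(sep)]
        if len(parts) > 7:
            raise FormatError(f"lineage has more than 7 ranks: {text!r}")
        parts += [UNKNOWN] * (7 - len(parts))
        parts = [p if p else UNKNOWN for p in parts]
        fixed: list[str] = []
        truncating = False
        for p in parts:
            if p == UNKNOWN:
                truncating = True
            if truncating and p != UNKNOWN:
                logger.warning("lineage %r not prefix-closed; truncating from first UNKNOWN", text)
                truncating = True
                p = UNKNOWN
            fixed.append(UNKNOWN if truncating else p)
        return cls(tuple(fixed))

    def truncate(self, n_trusted: int) -> "Lineage":
        """Keep the first ``n_trusted`` ranks, everything below becomes UNKNOWN."""
        n = max(0, min(7, n_trusted))
        return Lineage(tuple(list(self.ranks[:n]) + [UNKNOWN] * (7 - n)))

    def depth(self) -> int:
        """Number of resolved (non-UNKNOWN) leading ranks."""
        for i, r in enumerate(self.ranks):
            if r == UNKNOWN:
                return i
        return 7

    def __str__(self) -> str:
        return ";".join(self.ranks)


@dataclass
class BinMetadata:
    """Quality and membership of one metagenome bin (draft genome)."""

    bin_id: str
    completeness: float
    contamination: float
    size_bp: int
    contig_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0 <= self.completeness <= 100):
            raise FormatError(f"bin {self.bin_id}: completeness {self.completeness} outside [0,100]")
        if self.contamination < 0:
            raise FormatError(f"bin {self.bin_id}: negative contamination")
        if self.size_bp < 0:
            raise FormatError(f"bin {self.bin_id}: negative size")


@dataclass
class OtuTable:
    """OTU x sample count matrix; source of the read-count and abundance filters."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_otus, n_samples), integer
    sample_datasets: dict[str, str] | None = None  # optional sample -> dataset label

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if self.counts.size and not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("OTU counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and (self.counts < 0).any():
            raise FormatError("OTU counts must be non-negative")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise FormatError("duplicate OTU ids in table")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in table")

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)


# --------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) FASTA file into validated records.

    Order-preserving; duplicate ids, empty records and non-IUPAC characters
    are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), desc=desc))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.desc)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# --------------------------------------------------------------------------
# OTU tables

def read_otu_table(path: str | os.PathLike, dialect: str = "auto") -> OtuTable:
    """Read an OTU count table from TSV (rows=OTUs) or dense BIOM-JSON 1.0.

    ``dialect`` is ``tsv``, ``biom`` or ``auto`` (sniffed from the first
    byte: BIOM-JSON starts with ``{``).
    """
    path = os.fspath(path)
    if dialect == "auto":
        with open(path) as fh:
            first = fh.read(1)
        dialect = "biom" if first == "{" else "tsv"
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        if df.columns[0] != "otu_id":
            raise FormatError(f"OTU table must start with an 'otu_id' column, got {df.columns[0]!r}")
        otu_ids = df["otu_id"].tolist()
        sample_ids = [str(c) for c in df.columns[1:]]
        mat = df.iloc[:, 1:].to_numpy()
    elif dialect == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("matrix_type") != "dense":
            raise FormatError("only dense BIOM-JSON (format 1.0) is supported")
        otu_ids = [row["id"] for row in doc["rows"]]
        sample_ids = [col["id"] for col in doc["columns"]]
        mat = np.asarray(doc["data"])
    else:
        raise ValueError(f"unknown OTU-table dialect {dialect!r}")
    try:
        mat = np.asarray(mat, dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric count in OTU table {path}") from exc
    if np.isnan(mat).any():
        raise FormatError(f"non-numeric count in OTU table {path}")
    return OtuTable(otu_ids=otu_ids, sample_ids=sample_ids, counts=mat)


def write_otu_table(table: OtuTable, path: str | os.PathLike) -> None:
    df = table.to_dataframe()
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


# --------------------------------------------------------------------------
# Lineages and bins

def read_lineages(path: str | os.PathLike) -> dict[str, Lineage]:
    """Read a ``seq_id<TAB>lineage`` TSV into a map keyed by sequence id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("seq_id", "lineage"):
        if col not in df.columns:
            raise FormatError(f"lineage TSV missing required column {col!r}")
    out: dict[str, Lineage] = {}
    for _, row in df.iterrows():
        sid = row["seq_id"]
        if sid in out:
            raise FormatError(f"duplicate seq_id {sid!r} in lineage table")
        out[sid] = Lineage.from_string(row["lineage"])
    return out


def write_lineages(lineages: Mapping[str, Lineage], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {"seq_id": list(lineages), "lineage": [str(v) for v in lineages.values()]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_bin_metadata(path: str | os.PathLike) -> dict[str, BinMetadata]:
    """Read bin membership/quality TSV (one row per contig) into per-bin metadata."""
    df = pd.read_csv(path, sep="\t", dtype={"bin_id": str, "contig_id": str})
    required = ("bin_id", "contig_id", "completeness", "contamination", "size_bp")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"bin TSV missing required column {col!r}")
    bins: dict[str, BinMetadata] = {}
    owner: dict[str, str] = {}
    for _, row in df.iterrows():
        bid = row["bin_id"]
        cid = row["contig_id"]
        if cid in owner and owner[cid] != bid:
            raise FormatError(f"contig {cid!r} assigned to both {owner[cid]!r} and {bid!r}")
        owner[cid] = bid
        if bid not in bins:
            bins[bid] = BinMetadata(
                bin_id=bid,
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                size_bp=int(row["size_bp"]),
            )
        bins[bid].contig_ids.add(cid)
    return bins


def write_bin_metadata(bins: Mapping[str, BinMetadata], path: str | os.PathLike) -> None:
    rows = []
    for b in bins.values():
        for cid in sorted(b.contig_ids):
            rows.append(
                {
                    "bin_id": b.bin_id,
                    "contig_id": cid,
                    "completeness": b.completeness,
                    "contamination": b.contamination,
                    "size_bp": b.size_bp,
                }
            )
    pd.DataFrame(rows, columns=["bin_id", "contig_id", "completeness", "contamination", "size_bp"]).to_csv(
        path, sep="\t", index=False
    )
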