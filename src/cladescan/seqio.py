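"""Sequence and annotation I/O.

FASTA reading (Biopython-backed), six-frame translation of nucleotide
reads, and the tab-separated annotation table that the pipeline emits.
Coordinates everywhere in the package are 1-based inclusive on the
amino-acid read, matching HMMER domtblout envelope coordinates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq

AA_CHARS = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}
NT_CHARS = set("ACGTU") | set("RYSWKMBDHVN")  # IUPAC ambiguity codes


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, naming the offending record."""


@dataclass(frozen=True)
class SeqRecord:
    """A read or ORF sequence.

    ``alphabet`` is ``"aa"`` or ``"nt"``; sequences are stored uppercase.
    """

    id: str
    seq: str
    alphabet: str = "aa"

    def __post_init__(self) -> None:
        if not self.seq:
            raise FastaParseError(f"record {self.id!r} has an empty sequence")
        if self.alphabet not in ("aa", "nt"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadAnnotation:
    """Final non-overlapping domain architecture of one read.

    ``hits`` is ordered by alignment start; after the last selection
    filter no two hits share 10 or more residues.
    """

    read_id: str
    hits: list = field(default_factory=list)
    source_tool: str = "cladescan"

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def read_fasta(path: str | Path, alphabet: str = "aa") -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects.

    The record id is the token before the first whitespace; sequences are
    uppercased and input order is preserved.  An empty sequence raises
    :class:`FastaParseError` naming the record.
    """
    records: list[SeqRecord] = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(SeqRecord(id=rec.id, seq=seq, alphabet=alphabet))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def six_frame_translate(rec: SeqRecord) -> list[SeqRecord]:
    """Translate a nucleotide read in all six reading frames.

    Frames +1, +2, +3 read the forward strand at offsets 0, 1, 2; frames
    -1, -2, -3 read the reverse complement likewise.  Stop codons are
    rendered as ``*`` and a trailing partial codon is dropped.  Output ids
    carry a ``_frame{±k}`` suffix.
    """
    if rec.alphabet != "nt":
        raise ValueError(f"six_frame_translate requires a nucleotide record, got {rec.alphabet}")
    bad = set(rec.seq) - NT_CHARS
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters in {rec.id!r}: {sorted(bad)}")
    fwd = Seq(rec.seq.replace("U", "T"))
    rev = fwd.reverse_complement()
    out: list[SeqRecord] = []
    for strand, label in ((fwd, "+"), (rev, "-")):
        for offset in range(3):
            sub = strand[offset : offset + 3 * ((len(strand) - offset) // 3)]
            aa = str(sub.translate(table=1))
            if aa:
                out.append(SeqRecord(id=f"{rec.id}_frame{label}{offset + 1}", seq=aa, alphabet="aa"))
    return out


#: Fixed column order of the annotation table.
ANNOTATION_COLUMNS = [
    "read_id",
    "domain_acc",
    "model_id",
    "model_type",
    "ali_start",
    "ali_end",
    "bit_score",
    "mean_bit_score",
    "evalue",
    "identity_pct",
    "posterior",
    "ranking_score",
    "source_tool",
]


def write_annotations(annos: Iterable[ReadAnnotation], path: str | Path) -> None:
    """Write annotations as a TSV with one row per accepted hit.

    ``evalue`` is written as ``NA`` when absent.  The table round-trips
    bit-exactly through :func:`read_annotations` (floats via repr).
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for anno in annos:
            for hit in anno.hits:
                writer.writerow(
                    [
                        anno.read_id,
                        hit.domain_acc,
                        hit.model_id,
                        hit.model_type,
                        hit.ali_start,
                        hit.ali_end,
                        repr(hit.bit_score),
                        repr(hit.mean_bit_score),
                        "NA" if hit.evalue is None else repr(hit.evalue),
                        repr(hit.identity_pct),
                        "NA" if hit.posterior is None else repr(hit.posterior),
                        "NA" if hit.ranking_score is None else repr(hit.ranking_score),
                        anno.source_tool,
                    ]
                )


def read_annotations(path: str | Path) -> list[ReadAnnotation]:
    """Inverse of :func:`write_annotations` (grouped by read, input order)."""
    from cladescan.search_backend import DomainHit

    annos: dict[tuple[str, str], ReadAnnotation] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != ANNOTATION_COLUMNS:
            raise ValueError(f"unexpected annotation header in {path}")
        for row in reader:
            rec = dict(zip(ANNOTATION_COLUMNS, row))
            key = (rec["read_id"], rec["source_tool"])
            anno = annos.setdefault(
                key, ReadAnnotation(read_id=rec["read_id"], source_tool=rec["source_tool"])
            )
            anno.hits.append(
                DomainHit(
                    read_id=rec["read_id"],
                    model_id=rec["model_id"],
                    domain_acc=rec["domain_acc"],
                    model_type=rec["model_type"],
                    ali_start=int(rec["ali_start"]),
                    ali_end=int(rec["ali_end"]),
                    bit_score=float(rec["bit_score"]),
                    mean_bit_score=float(rec["mean_bit_score"]),
                    identity_pct=float(rec["identity_pct"]),
                    evalue=None if rec["evalue"] == "NA" else float(rec["evalue"]),
                    posterior=None if rec["posterior"] == "NA" else float(rec["posterior"]),
                    ranking_score=None if rec["ranking_score"] == "NA" else float(rec["ranking_score"]),
                )
            )
    return list(annos.values())
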