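"""On-disk form of synthetic fixtures (used by the CLI `simulate`)."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

from cladescan.model_library import MANIFEST_COLUMNS, ModelLibrary
from cladescan.search_backend import DomainHit, save_pssm
from cladescan.seqio import ReadAnnotation, SeqRecord, write_fasta
from cladescan.synthetic_fixtures import PlantedTruth, SyntheticFamily

TRUTH_COLUMNS = ["read_id", "domain_acc", "start", "end", "clade"]


def truths_as_annotations(truths: Sequence[PlantedTruth]) -> list[ReadAnnotation]:
    """Ground truth as annotation records (for `evaluate`)."""
    by_read: dict[str, ReadAnnotation] = {}
    for t in truths:
        anno = by_read.setdefault(t.read_id, ReadAnnotation(read_id=t.read_id, source_tool="truth"))
        anno.hits.append(
            DomainHit(
                read_id=t.read_id,
                model_id="truth",
                domain_acc=t.domain_acc,
                model_type="SCM",
                ali_start=t.start,
                ali_end=t.end,
                bit_score=0.0,
                mean_bit_score=0.0,
            )
        )
    return [by_read[k] for k in sorted(by_read)]


def write_truths(truths: Sequence[PlantedTruth], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for t in truths:
            writer.writerow([t.read_id, t.domain_acc, t.start, t.end, t.clade])


def read_truths(path: str | Path) -> list[PlantedTruth]:
    out: list[PlantedTruth] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth header in {path}")
        for rid, acc, s, e, clade in reader:
            out.append(PlantedTruth(rid, acc, int(s), int(e), clade))
    return out


def export_fixture(
    families: Sequence[SyntheticFamily],
    lib: ModelLibrary,
    reads: Sequence[SeqRecord],
    truths: Sequence[PlantedTruth],
    out_dir: str | Path,
) -> None:
    """Write a complete runnable fixture: manifest + serialized profiles,
    per-domain SEED FASTAs, reads and ground truth."""
    out = Path(out_dir)
    (out / "profiles").mkdir(parents=True, exist_ok=True)
    (out / "seeds").mkdir(exist_ok=True)
    with open(out / "library.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for m in lib:
            rel = f"profiles/{m.model_id}.pssm.tsv"
            save_pssm(m.profile_ref, out / rel)
            writer.writerow([m.model_id, m.domain_acc, m.model_type, m.clade, rel])
    for fam in families:
        rows = fam.all_seed_rows()
        write_fasta(
            [SeqRecord(id=f"{fam.domain_acc}_seed{i}", seq=row) for i, row in enumerate(rows)],
            out / "seeds" / f"{fam.domain_acc}.fasta",
        )
    write_fasta(reads, out / "reads.fasta")
    write_truths(truths, out / "truth.tsv")
    from cladescan.seqio import write_annotations

    write_annotations(truths_as_annotations(truths), out / "truth_annotations.tsv")
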