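"""Functional abundance profiling and annotation evaluation.

Accepted domains are mapped to GO classes through a pfam2go table
(external2go dialect) and counted per class.  Two normalisations are
provided: a within-sample one (each class divided by the most represented
class of the sample) and the cross-sample abundance N^S_I, the domain
count per megabase scaled by the average sample size so that samples of
different depth become comparable.  Evaluation against a ground truth is
read-level: a predicted domain is a true positive when the same read
carries an unmatched truth hit of the same domain (or of the same clan in
clan-aware mode).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from cladescan.model_library import ModelLibrary
from cladescan.seqio import ReadAnnotation

_PFAM2GO_RE = re.compile(r"^Pfam:(\S+)\s+\S+\s*>\s*GO:.*?;\s*(GO:\d{7})\s*$")


def load_pfam2go(path: str | Path) -> dict[str, set[str]]:
    """Parse a pfam2go mapping (external2go text dialect).

    Lines look like ``Pfam:PF00001 7tm_1 > GO:GPCR activity ; GO:0004930``;
    ``!`` lines are comments.  A domain may map to several GO terms.
    """
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            m = _PFAM2GO_RE.match(line)
            if not m:
                raise ValueError(f"{path}:{lineno}: malformed pfam2go line: {line!r}")
            acc, go = m.groups()
            mapping.setdefault(acc, set()).add(go)
    return mapping


UNMAPPED = "unmapped"


def class_counts(
    annotations: Iterable[ReadAnnotation],
    mapping: dict[str, set[str]],
    goslim_terms: Optional[set[str]] = None,
) -> dict[str, int]:
    """Count accepted domain hits per GO functional class.

    Each hit contributes one count to every class its domain maps to
    (restricted to ``goslim_terms`` when given); domains with no eligible
    mapping are counted under ``"unmapped"``.
    """
    counts: dict[str, int] = {}
    for anno in annotations:
        for hit in anno.hits:
            terms = mapping.get(hit.domain_acc, set())
            if goslim_terms is not None:
                terms = terms & goslim_terms
            if not terms:
                counts[UNMAPPED] = counts.get(UNMAPPED, 0) + 1
            else:
                for t in sorted(terms):
                    counts[t] = counts.get(t, 0) + 1
    return counts


def within_sample_normalise(counts: dict[str, int]) -> dict[str, float]:
    """Divide each class count by the sample's most represented class.

    Values land in [0, 1] with the maximal class (all of them, on ties)
    at exactly 1.  All-zero input is an error.
    """
    if not counts or max(counts.values()) <= 0:
        raise ValueError("within-sample normalisation needs at least one non-zero count")
    top = max(counts.values())
    return {cls: n / top for cls, n in counts.items()}


def cross_sample_abundance(count: int, sample_size_mb: float, all_sizes_mb: Sequence[float]) -> float:
    """Cross-sample normalised abundance N^S_I.

    The domain count per megabase of the sample, multiplied by the
    average size of all samples — the expected count if every sample had
    the same (average) size.
    """
    if sample_size_mb <= 0 or any(s <= 0 for s in all_sizes_mb):
        raise ValueError("sample sizes must be positive")
    return (count / sample_size_mb) * (sum(all_sizes_mb) / len(all_sizes_mb))


def sample_size_mb(annotations_or_reads: Iterable, residues_per_read: Optional[int] = None) -> float:
    """Helper: sample size in megabases from read records (Σ length / 1e6)."""
    total = 0
    for rec in annotations_or_reads:
        total += len(rec.seq) if hasattr(rec, "seq") else int(residues_per_read or 0)
    return total / 1e6


@dataclass
class AbundanceTable:
    """Per-sample functional-class domain counts and normalised values."""

    sample_id: str
    class_counts: dict[str, int]
    sample_size_mb: Optional[float] = None
    normalised: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_annotations(
        cls,
        sample_id: str,
        annotations: Iterable[ReadAnnotation],
        mapping: dict[str, set[str]],
        goslim_terms: Optional[set[str]] = None,
        sample_size_mb: Optional[float] = None,
    ) -> "AbundanceTable":
        counts = class_counts(annotations, mapping, goslim_terms)
        table = cls(sample_id=sample_id, class_counts=counts, sample_size_mb=sample_size_mb)
        if counts and max(counts.values()) > 0:
            table.normalised = within_sample_normalise(counts)
        return table


def evaluate(
    pred: Iterable[ReadAnnotation],
    truth: Iterable[ReadAnnotation],
    clan_map: Optional[dict[str, str]] = None,
) -> dict[str, float]:
    """Read-level precision/recall/F against a ground truth.

    A predicted hit is a true positive when its read carries a
    still-unmatched truth hit of the same domain accession — or, in
    clan-aware mode, of any domain in the same clan.  Each truth hit is
    matched at most once; FP are unmatched predictions, FN unmatched
    truths, and F = 2TP / (2TP + FP + FN).
    """

    def by_read(annos: Iterable[ReadAnnotation]) -> dict[str, list]:
        out: dict[str, list] = {}
        for a in annos:
            out.setdefault(a.read_id, []).extend(a.hits)
        return out

    pred_ix, truth_ix = by_read(pred), by_read(truth)
    tp = fp = 0
    matched: dict[str, list[bool]] = {rid: [False] * len(h) for rid, h in truth_ix.items()}

    def same_class(acc_a: str, acc_b: str) -> bool:
        if acc_a == acc_b:
            return True
        if clan_map is not None:
            ca, cb = clan_map.get(acc_a), clan_map.get(acc_b)
            return ca is not None and ca == cb
        return False

    for rid in sorted(pred_ix):
        truths = truth_ix.get(rid, [])
        flags = matched.get(rid, [])
        for hit in pred_ix[rid]:
            hit_tp = False
            for i, t in enumerate(truths):
                if not flags[i] and same_class(hit.domain_acc, t.domain_acc):
                    flags[i] = True
                    hit_tp = True
                    break
            if hit_tp:
                tp += 1
            else:
                fp += 1
    fn = sum(flag.count(False) for flag in matched.values())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return {
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "precision": precision,
        "recall": recall,
        "F": f,
    }


def clade_usage_histogram(
    annotations: Iterable[ReadAnnotation], lib: ModelLibrary
) -> dict[str, dict[str, float]]:
    """Clades of origin of the CCMs used in an annotation set.

    Returns ``{"counts": ..., "proportions": ...}``; proportions sum to 1
    when any CCM hit exists.
    """
    counts: dict[str, int] = {}
    for anno in annotations:
        for hit in anno.hits:
            if hit.model_type != "CCM":
                continue
            model = lib.models.get(hit.model_id)
            clade = model.clade if model is not None else ""
            counts[clade] = counts.get(clade, 0) + 1
    total = sum(counts.values())
    proportions = {c: n / total for c, n in counts.items()} if total else {}
    return {"counts": counts, "proportions": proportions}


def write_abundance_tsv(tables: Sequence[AbundanceTable], path: str | Path) -> None:
    """Write per-sample abundance with both normalisations as TSV."""
    sizes = [t.sample_size_mb for t in tables if t.sample_size_mb]
    with open(path, "w") as fh:
        fh.write("sample\tclass\tcount\twithin_norm\tcross_norm\n")
        for t in tables:
            for cls in sorted(t.class_counts):
                n = t.class_counts[cls]
                within = t.normalised.get(cls, 0.0)
                if t.sample_size_mb and sizes:
                    cross = repr(cross_sample_abundance(n, t.sample_size_mb, sizes))
                else:
                    cross = "NA"
                fh.write(f"{t.sample_id}\t{cls}\t{n}\t{within!r}\t{cross}\n")
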