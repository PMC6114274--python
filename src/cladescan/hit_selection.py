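"""Three-stage selection of domain hits on a read, plus annotation merging.

Stage 1 removes redundant same-domain hits (overlap covering at least 85%
of both hit lengths keeps only the higher bit-score), independently for
CCMs and SCMs.  Stage 2 applies the two-dimensional gathering threshold:
a hit survives only with bit-score strictly above the domain's lower
bound (smallest training negative) and posterior probability of being a
true positive strictly above the cut (0.9 by default; 0.85 is the
permissive variant for very short reads).  Stage 3 ranks hits by
posterior × identity and greedily resolves residual overlaps, discarding
any hit sharing at least 10 residues with a better-ranked one — the
result is the read's non-overlapping domain architecture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from cladescan.bayes_space import ProbabilitySpace, posterior as _posterior
from cladescan.model_library import ModelLibrary
from cladescan.search_backend import DomainHit, scan_model
from cladescan.seqio import ReadAnnotation, SeqRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionParams:
    """Tunables of the three selection stages."""

    overlap_frac: float = 0.85
    prob_threshold: float = 0.90
    shared_residues: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.overlap_frac <= 1):
            raise ValueError("overlap_frac must be in (0, 1]")
        if not (0 < self.prob_threshold < 1):
            raise ValueError("prob_threshold must be in (0, 1)")
        if self.shared_residues < 1:
            raise ValueError("shared_residues must be >= 1")


def filter1_dedupe_same_domain(
    hits: Sequence[DomainHit], params: SelectionParams = SelectionParams()
) -> list[DomainHit]:
    """Remove redundant same-domain hits within one read.

    Processed separately per model class (CCM/SCM) and per domain: hits
    are visited by descending bit-score (ties: longer hit, then model_id)
    and dropped when the overlap with an already retained same-domain hit
    covers at least ``overlap_frac`` of both hit lengths.  Hits of
    different domains never suppress each other, and two genuinely
    distinct occurrences of the same domain on a read both survive.
    """
    retained: list[DomainHit] = []
    groups: dict[tuple[str, str], list[DomainHit]] = {}
    for h in hits:
        groups.setdefault((h.model_type, h.domain_acc), []).append(h)
    for key in sorted(groups):
        group = sorted(groups[key], key=lambda h: (-h.bit_score, -h.length, h.model_id))
        kept: list[DomainHit] = []
        for h in group:
            redundant = False
            for k in kept:
                ov = h.overlap(k)
                if ov >= params.overlap_frac * h.length and ov >= params.overlap_frac * k.length:
                    redundant = True
                    break
            if not redundant:
                kept.append(h)
        retained.extend(kept)
    retained.sort(key=lambda h: (h.ali_start, h.ali_end, h.model_id))
    return retained


def filter2_probability(
    hits: Sequence[DomainHit],
    spaces: dict[tuple[str, str], ProbabilitySpace],
    params: SelectionParams = SelectionParams(),
) -> list[DomainHit]:
    """Apply the two-dimensional gathering threshold.

    A hit is kept iff its bit-score is strictly greater than the space's
    lower bound (smallest training negative) and its posterior is strictly
    greater than ``prob_threshold``.  The posterior is stored on the hit.
    Hits whose (domain, model class) has no fitted space are dropped with
    a warning.
    """
    out: list[DomainHit] = []
    missing = 0
    for h in hits:
        space = spaces.get((h.domain_acc, h.model_type))
        if space is None:
            missing += 1
            continue
        p = _posterior(space, h.bit_score, h.mean_bit_score)
        h.posterior = p
        if h.bit_score > space.min_neg_bit and p > params.prob_threshold:
            out.append(h)
    if missing:
        logger.warning("filter2: %d hit(s) dropped for lack of a fitted space", missing)
    return out


def filter3_rank_resolve(
    hits: Sequence[DomainHit], params: SelectionParams = SelectionParams()
) -> list[DomainHit]:
    """Greedy overlap resolution by ranking score.

    The ranking score maps the hit's statistical significance (the
    posterior, already in [0,1]) times its identity fraction against the
    model consensus.  Hits are taken in decreasing rank (ties: bit-score
    descending, then model_id) and discarded when sharing at least
    ``shared_residues`` read positions with a better-ranked retained hit.
    Output is sorted by alignment start.
    """
    scored: list[DomainHit] = []
    for h in hits:
        if h.posterior is None:
            raise ValueError(f"hit {h.model_id}@{h.read_id} lacks a posterior (run filter 2 first)")
        h.ranking_score = h.posterior * (h.identity_pct / 100.0)
        scored.append(h)
    scored.sort(key=lambda h: (-h.ranking_score, -h.bit_score, h.model_id))
    retained: list[DomainHit] = []
    for h in scored:
        if all(h.overlap(k) < params.shared_residues for k in retained):
            retained.append(h)
    retained.sort(key=lambda h: (h.ali_start, h.ali_end, h.model_id))
    return retained


def annotate_read(
    read: SeqRecord,
    lib: ModelLibrary,
    spaces: dict[tuple[str, str], ProbabilitySpace],
    params: SelectionParams = SelectionParams(),
    min_overlap: int = 8,
    raw_hits: Optional[Sequence[DomainHit]] = None,
    counters: Optional[dict[str, int]] = None,
) -> ReadAnnotation:
    """Scan every library model over the read and run the three filters.

    ``raw_hits`` may supply externally parsed hits (domtblout/PSI-BLAST
    routes) instead of the built-in scanner.  ``counters``, when given,
    accumulates the per-stage funnel (raw / after each filter).
    """
    if raw_hits is None:
        hits: list[DomainHit] = []
        for model in lib:
            hits.extend(scan_model(model, read, min_overlap=min_overlap))
    else:
        hits = list(raw_hits)
    f1 = filter1_dedupe_same_domain(hits, params)
    f2 = filter2_probability(f1, spaces, params)
    f3 = filter3_rank_resolve(f2, params)
    if counters is not None:
        counters["raw"] = counters.get("raw", 0) + len(hits)
        counters["after_f1"] = counters.get("after_f1", 0) + len(f1)
        counters["after_f2"] = counters.get("after_f2", 0) + len(f2)
        counters["after_f3"] = counters.get("after_f3", 0) + len(f3)
    return ReadAnnotation(read_id=read.id, hits=f3)


def combine_annotations(
    primary: Iterable[ReadAnnotation], secondary: Iterable[ReadAnnotation]
) -> list[ReadAnnotation]:
    """Merge two annotation sets, primary-first.

    All primary annotations are kept verbatim; a secondary annotation is
    added only for reads the primary tool left unannotated (no primary
    annotation with at least one hit).  Duplicate read ids within one
    input are an error.
    """

    def index(annos: Iterable[ReadAnnotation], name: str) -> dict[str, ReadAnnotation]:
        out: dict[str, ReadAnnotation] = {}
        for a in annos:
            if a.read_id in out:
                raise ValueError(f"duplicate read_id {a.read_id!r} in {name} annotations")
            out[a.read_id] = a
        return out

    prim = index(primary, "primary")
    sec = index(secondary, "secondary")
    annotated = {rid for rid, a in prim.items() if len(a) > 0}
    combined = list(prim.values())
    combined.extend(a for rid, a in sorted(sec.items()) if rid not in annotated)
    return combined
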