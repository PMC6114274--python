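"""High-level glue: threshold training and read annotation in bulk.

These functions tie the per-domain and per-read primitives into the two
stages a user actually runs: the pre-computation of gathering thresholds
for every domain of a library, and the annotation of a read set against
those thresholds.  The CLI wraps these directly.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from cladescan.bayes_space import ProbabilitySpace, fit_space
from cladescan.hit_selection import SelectionParams, annotate_read
from cladescan.model_library import ModelLibrary
from cladescan.seqio import ReadAnnotation, SeqRecord, six_frame_translate
from cladescan.training_set import (
    FragmentParams,
    UnlearnableDomainError,
    build_training_set,
)

logger = logging.getLogger(__name__)


def train_gathering_thresholds(
    lib: ModelLibrary,
    seed_alignments: dict[str, Sequence[str]],
    rng: np.random.Generator,
    params: FragmentParams = FragmentParams(),
    skip_failures: bool = False,
    **build_kwargs,
) -> tuple[dict[tuple[str, str], ProbabilitySpace], list[dict]]:
    """Fit one probability space per (domain, model class).

    ``seed_alignments`` maps each domain accession to its SEED rows.  The
    returned summary holds per-domain n_pos/n_neg counts per class.  An
    unlearnable domain raises unless ``skip_failures``.
    """
    spaces: dict[tuple[str, str], ProbabilitySpace] = {}
    summary: list[dict] = []
    for acc in sorted(seed_alignments):
        scm, ccms = lib.models_for_domain(acc)
        try:
            instances = build_training_set(
                seed_alignments[acc], scm, ccms, acc, rng, params=params, **build_kwargs
            )
            for mtype in ("SCM", "CCM"):
                sub = [t for t in instances if t.model_type == mtype]
                if not sub:
                    continue
                space = fit_space(sub)
                spaces[(acc, mtype)] = space
                summary.append(
                    {"domain_acc": acc, "model_type": mtype, "n_pos": space.n_pos, "n_neg": space.n_neg}
                )
        except (UnlearnableDomainError, ValueError) as exc:
            if not skip_failures:
                raise
            logger.warning("domain %s skipped: %s", acc, exc)
            summary.append({"domain_acc": acc, "model_type": "-", "error": str(exc)})
    return spaces, summary


def annotate_reads(
    reads: Sequence[SeqRecord],
    lib: ModelLibrary,
    spaces: dict[tuple[str, str], ProbabilitySpace],
    params: SelectionParams = SelectionParams(),
    min_overlap: int = 8,
    translate: bool = False,
) -> tuple[list[ReadAnnotation], dict[str, int]]:
    """Annotate a read set; returns annotations plus the filter funnel.

    With ``translate`` the inputs are nucleotide reads: all six frames
    are annotated and each frame appears as its own record.
    """
    if translate:
        frames: list[SeqRecord] = []
        for rec in reads:
            frames.extend(six_frame_translate(rec))
        reads = frames
    counters: dict[str, int] = {}
    annotations = [
        annotate_read(read, lib, spaces, params=params, min_overlap=min_overlap, counters=counters)
        for read in reads
    ]
    return annotations, counters
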