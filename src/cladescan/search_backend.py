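"""Search backends producing domain hits.

Three routes yield :class:`DomainHit` records: parsers for HMMER3
``domtblout`` and PSI-BLAST tabular files (the engines used for SCMs and
CCMs respectively when real profile searches are available), and a
self-contained ungapped PSSM scanner so the whole pipeline runs without
external binaries.

Every hit carries the two coordinates of the gathering-threshold space:
the bit-score of the match and the mean-bit-score (bit-score divided by
the hit length on the read).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from cladescan.seqio import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_N_AA = 20


@dataclass(slots=True)
class DomainHit:
    """A scored match of one model on one read.

    Coordinates are 1-based inclusive on the amino-acid read.  The
    invariant ``mean_bit_score * (ali_end - ali_start + 1) == bit_score``
    holds to 1e-6 relative tolerance.  ``posterior`` and ``ranking_score``
    are filled by the selection filters.
    """

    read_id: str
    model_id: str
    domain_acc: str
    model_type: str
    ali_start: int
    ali_end: int
    bit_score: float
    mean_bit_score: float
    identity_pct: float = 100.0
    evalue: Optional[float] = None
    posterior: Optional[float] = None
    ranking_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise ValueError(f"hit on {self.read_id}: ali_start > ali_end")

    @property
    def length(self) -> int:
        return self.ali_end - self.ali_start + 1

    def overlap(self, other: "DomainHit") -> int:
        """Number of read residues shared with another hit."""
        return max(0, min(self.ali_end, other.ali_end) - max(self.ali_start, other.ali_start) + 1)


# ---------------------------------------------------------------------------
# Toy PSSM backend
# ---------------------------------------------------------------------------


class PSSM:
    """An ungapped position-specific scoring matrix in bits.

    Log-odds are taken against a uniform 1/20 amino-acid background.
    Ambiguity characters (X, *) on the read contribute zero bits and are
    excluded from identity computation.
    """

    def __init__(self, logodds: np.ndarray, consensus: str):
        logodds = np.asarray(logodds, dtype=float)
        if logodds.ndim != 2 or logodds.shape[1] != _N_AA:
            raise ValueError("logodds must be (columns, 20)")
        if logodds.shape[0] != len(consensus):
            raise ValueError("consensus length must match column count")
        self.logodds = logodds
        self.consensus = consensus
        # extra zero column so ambiguity codes can be gathered as index 20
        self._lo_ext = np.hstack([logodds, np.zeros((logodds.shape[0], 1))])

    def __len__(self) -> int:
        return self.logodds.shape[0]


def build_pssm(alignment: Sequence[str], pseudocount: float = 1.0) -> PSSM:
    """Build a PSSM from an ungapped-or-gapped alignment.

    Per column, ``p(aa) = (count + pseudocount) / (rows + 20 * pseudocount)``;
    gaps and ambiguity codes add no counts.  Log-odds are in bits against
    the uniform background; the consensus is the argmax residue per column
    (ties broken alphabetically).
    """
    rows = [s.upper() for s in alignment]
    if len(rows) < 2:
        raise ValueError("alignment needs at least 2 rows")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("ragged alignment")
    counts = np.zeros((ncol, _N_AA))
    for row in rows:
        for j, ch in enumerate(row):
            i = _AA_INDEX.get(ch)
            if i is not None:
                counts[j, i] += 1
    probs = (counts + pseudocount) / (len(rows) + _N_AA * pseudocount)
    with np.errstate(divide="ignore"):
        logodds = np.log2(probs * _N_AA)
    consensus = "".join(ALPHABET[j] for j in counts.argmax(axis=1))
    return PSSM(logodds, consensus)


def encode_aa(seq: str) -> np.ndarray:
    """Encode an amino-acid string; ambiguity codes (X, *) map to 20."""
    return np.fromiter((_AA_INDEX.get(ch, _N_AA) for ch in seq), dtype=np.intp, count=len(seq))


_DIAG_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _diag_index(n_col: int, n_read: int) -> np.ndarray:
    key = (n_col, n_read)
    d = _DIAG_CACHE.get(key)
    if d is None:
        i = np.arange(n_read)[None, :]
        j = np.arange(n_col)[:, None]
        d = (i - j + n_col - 1).ravel()
        _DIAG_CACHE[key] = d
    return d


def scan_pssm(
    profile: PSSM,
    read: SeqRecord,
    min_overlap: int = 8,
    model_id: str = "",
    domain_acc: str = "",
    model_type: str = "SCM",
) -> list[DomainHit]:
    """Score every ungapped placement of the model over the read.

    Terminal overhangs are allowed so domain fragments at read edges still
    score, as long as at least ``min_overlap`` columns align.  All
    placements with positive bit-score survive a non-maximum suppression
    of placements within one column shift of a higher-scoring one.
    """
    n_col, n_read = len(profile), len(read.seq)
    idx = encode_aa(read.seq)
    amat = profile._lo_ext[:, idx]  # (n_col, n_read)
    ndiag = n_col + n_read - 1
    scores = np.bincount(_diag_index(n_col, n_read), weights=amat.ravel(), minlength=ndiag)

    offsets = np.arange(ndiag) - (n_col - 1)  # read index of model column 0
    overlap = np.minimum(np.minimum(n_col, n_read), np.minimum(n_col + offsets, n_read - offsets))
    eligible = overlap >= min_overlap
    valid = eligible & (scores > 0)
    # suppress placements whose immediate (eligible) neighbour scores higher
    masked = np.where(eligible, scores, -np.inf)
    left = np.empty(ndiag)
    right = np.empty(ndiag)
    left[0], left[1:] = -np.inf, masked[:-1]
    right[-1], right[:-1] = -np.inf, masked[1:]
    keep = valid & (scores >= left) & (scores >= right)

    hits: list[DomainHit] = []
    for d in np.flatnonzero(keep):
        o = int(offsets[d])
        start = max(0, o)  # 0-based read start
        end = min(n_read, n_col + o)  # exclusive
        j0 = start - o
        seg = read.seq[start:end]
        cons_seg = profile.consensus[j0 : j0 + (end - start)]
        hits.append(
            DomainHit(
                read_id=read.id,
                model_id=model_id,
                domain_acc=domain_acc,
                model_type=model_type,
                ali_start=start + 1,
                ali_end=end,
                bit_score=float(scores[d]),
                mean_bit_score=float(scores[d]) / (end - start),
                identity_pct=identity_of(seg, cons_seg),
            )
        )
    return hits


def scan_model(model, read: SeqRecord, min_overlap: int = 8) -> list[DomainHit]:
    """Scan a library :class:`~cladescan.model_library.DomainModel`."""
    profile = model.profile_ref
    if not isinstance(profile, PSSM):
        raise TypeError(f"model {model.model_id} has no in-memory PSSM profile")
    return scan_pssm(
        profile,
        read,
        min_overlap=min_overlap,
        model_id=model.model_id,
        domain_acc=model.domain_acc,
        model_type=model.model_type,
    )


def identity_of(read_segment: str, consensus_segment: str) -> float:
    """Percent identity over aligned columns.

    Columns where either side is an ambiguity code (X) or a stop (*) are
    excluded from the denominator; an empty denominator yields 0.
    """
    if len(read_segment) != len(consensus_segment):
        raise ValueError("segments must have equal length in ungapped mode")
    matches = 0
    compared = 0
    for a, b in zip(read_segment, consensus_segment):
        if a in "X*" or b in "X*":
            continue
        compared += 1
        if a == b:
            matches += 1
    return 100.0 * matches / compared if compared else 0.0


# ---------------------------------------------------------------------------
# Profile serialization
# ---------------------------------------------------------------------------


def save_pssm(profile: PSSM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#pssm\tv1\n")
        fh.write(f"#consensus\t{profile.consensus}\n")
        fh.write("col\t" + "\t".join(ALPHABET) + "\n")
        for j in range(len(profile)):
            fh.write(str(j) + "\t" + "\t".join(repr(float(x)) for x in profile.logodds[j]) + "\n")


def load_pssm(path: str | Path) -> PSSM:
    consensus = None
    rows: list[list[float]] = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#pssm"):
            raise ValueError(f"{path} is not a serialized profile")
        for line in fh:
            if line.startswith("#consensus"):
                consensus = line.rstrip("\n").split("\t")[1]
            elif line.startswith("col\t") or not line.strip():
                continue
            else:
                rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
    if consensus is None:
        raise ValueError(f"{path} lacks a consensus line")
    return PSSM(np.array(rows), consensus)


# ---------------------------------------------------------------------------
# Parsers for external search programs
# ---------------------------------------------------------------------------


def _resolve_model(name: str, lib) -> Optional[object]:
    if name in lib.models:
        return lib.models[name]
    return None


def parse_domtblout(
    path: str | Path,
    lib,
    reads: Optional[dict[str, SeqRecord]] = None,
) -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output (``--domtblout``).

    One hit per domain line, using envelope coordinates on the read and
    the per-domain bit-score; the mean-bit-score is the bit-score divided
    by the envelope length.  When ``reads`` is given, identity against the
    model consensus is computed over the envelope segment; otherwise it
    defaults to 100.  Unresolvable model names are skipped with a warning.
    """
    hits: list[DomainHit] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ValueError(f"{path}:{lineno}: malformed domtblout line ({len(fields)} fields)")
            target, query = fields[0], fields[3]
            model = _resolve_model(target, lib)
            read_id = query
            if model is None:
                # hmmsearch orientation: query is the model, target the read
                model = _resolve_model(query, lib)
                read_id = target
            if model is None:
                logger.warning("%s:%d: model %r not in library; line skipped", path, lineno, target)
                skipped += 1
                continue
            try:
                i_evalue = float(fields[12])
                dom_bits = float(fields[13])
                env_from, env_to = int(fields[19]), int(fields[20])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed domtblout line: {exc}") from exc
            if env_from > env_to or env_from < 1:
                raise ValueError(f"{path}:{lineno}: bad envelope coordinates {env_from}..{env_to}")
            length = env_to - env_from + 1
            identity = 100.0
            if reads is not None and read_id in reads:
                seg = reads[read_id].seq[env_from - 1 : env_to]
                hmm_from = int(fields[15])
                cons_seg = model.consensus[hmm_from - 1 : hmm_from - 1 + len(seg)]
                if len(cons_seg) == len(seg):
                    identity = identity_of(seg, cons_seg)
            hits.append(
                DomainHit(
                    read_id=read_id,
                    model_id=model.model_id,
                    domain_acc=model.domain_acc,
                    model_type=model.model_type,
                    ali_start=env_from,
                    ali_end=env_to,
                    bit_score=dom_bits,
                    mean_bit_score=dom_bits / length,
                    identity_pct=identity,
                    evalue=i_evalue,
                )
            )
    if skipped:
        logger.warning("%s: %d line(s) skipped (unresolvable model)", path, skipped)
    return hits


def parse_psiblast_tabular(path: str | Path, lib) -> list[DomainHit]:
    """Parse BLAST/PSI-BLAST ``outfmt 7``-style tabular output.

    Expected columns: query, subject, %identity, alignment length,
    mismatches, gap opens, q.start, q.end, s.start, s.end, evalue,
    bit-score.  PSI-BLAST emits the PSSM as the query, so whichever of the
    two ids resolves in the library is taken as the model; alignment
    coordinates on the other (the read) are used.
    """
    hits: list[DomainHit] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: malformed tabular line ({len(fields)} fields)")
            query, subject = fields[0], fields[1]
            model = _resolve_model(query, lib)
            if model is not None:
                read_id, s, e = subject, int(fields[8]), int(fields[9])
            else:
                model = _resolve_model(subject, lib)
                read_id, s, e = query, int(fields[6]), int(fields[7])
            if model is None:
                logger.warning("%s:%d: no library model in %r/%r; skipped", path, lineno, query, subject)
                skipped += 1
                continue
            if s > e:
                s, e = e, s
            if s < 1:
                raise ValueError(f"{path}:{lineno}: non-positive alignment coordinate {s}")
            bits = float(fields[11])
            length = e - s + 1
            hits.append(
                DomainHit(
                    read_id=read_id,
                    model_id=model.model_id,
                    domain_acc=model.domain_acc,
                    model_type=model.model_type,
                    ali_start=s,
                    ali_end=e,
                    bit_score=bits,
                    mean_bit_score=bits / length,
                    identity_pct=float(fields[2]),
                    evalue=float(fields[10]),
                )
            )
    if skipped:
        logger.warning("%s: %d line(s) skipped (unresolvable model)", path, skipped)
    return hits
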