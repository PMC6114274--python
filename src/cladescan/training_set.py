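"""Per-domain training sets for the two-dimensional gathering threshold.

Positives are short fragments cut from the domain's SEED sequences:
ladders of prefixes and suffixes of increasing length emulate the partial
domain copies found at read edges, and for large domains (>270 aa)
additional internal fragments emulate reads falling in the middle of the
domain.  Negatives are decoy sequences — 2-mer shuffles, reversals and
samples from an order-3 Markov model of the SEED — that a domain model
nevertheless matches; only the matched decoys enter the training set,
each contributing one (bit-score, mean-bit-score) point.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from cladescan.model_library import DomainModel
from cladescan.search_backend import ALPHABET, DomainHit, scan_model
from cladescan.seqio import SeqRecord

_N_AA = 20
_TUPLE_SPACE = _N_AA**4  # 160,000 4-tuples
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass(frozen=True)
class FragmentParams:
    """Positive-fragment construction constants.

    ``max_frac``/``max_len`` bound the terminal ladder (30% of the domain,
    at most 100 aa); the ladder step ``L`` depends on domain length
    (<15 aa: 1; 15–75 aa: 5; >75 aa: 10).  Domains longer than
    ``internal_threshold`` get ``internal_count`` internal fragments whose
    raw lengths are drawn from Normal(``internal_mean``,
    ``internal_sd``).
    """

    max_frac: float = 0.30
    max_len: int = 100
    L_small: int = 1
    L_mid: int = 5
    L_large: int = 10
    internal_threshold: int = 270
    internal_count: int = 10
    internal_mean: float = 50.0
    internal_sd: float = 25.0

    def step_for(self, length: int) -> int:
        if length < 15:
            return self.L_small
        if length <= 75:
            return self.L_mid
        return self.L_large


@dataclass(frozen=True)
class TrainingInstance:
    """A labelled point in the (bit-score, mean-bit-score) plane."""

    bit_score: float
    mean_bit_score: float
    label: str  # "positive" | "negative"
    model_type: str  # "SCM" | "CCM"
    domain_acc: str

    @property
    def distance(self) -> float:
        """Euclidean distance from the origin of the score plane."""
        return math.hypot(self.bit_score, self.mean_bit_score)


def sample_internal_length(params: FragmentParams, rng: np.random.Generator) -> int:
    """Raw internal-fragment length: Normal(mean, sd) rounded to int."""
    return int(round(rng.normal(params.internal_mean, params.internal_sd)))


def generate_positive_fragments(
    seq: str, params: FragmentParams = FragmentParams(), rng: Optional[np.random.Generator] = None
) -> list[str]:
    """Cut the positive fragments of one SEED sequence.

    Terminal ladders: with M = min(max_frac·len, max_len) and step L, the
    prefix and suffix lengths are n·L for n = 1..N where N is the smallest
    integer with M ≤ N·L (each capped at the sequence length).  For
    sequences longer than 270 aa, ten internal fragments are drawn from
    the middle region not covered by the ladders, with start uniform and
    raw length ~ Normal(50, 25) rounded and clipped to the available span.
    """
    n = len(seq)
    if n < 2:
        raise ValueError("sequence too short to fragment (need length >= 2)")
    m_cap = min(params.max_frac * n, float(params.max_len))
    step = params.step_for(n)
    n_steps = math.ceil(m_cap / step)
    lengths = [min(k * step, n) for k in range(1, n_steps + 1)]
    frags = [seq[:l] for l in lengths] + [seq[-l:] for l in lengths]
    if n > params.internal_threshold:
        if rng is None:
            rng = np.random.default_rng()
        term = min(n_steps * step, n)
        lo, hi = term, n - term  # 0-based middle region [lo, hi)
        for _ in range(params.internal_count):
            start = int(rng.integers(lo, max(lo + 1, hi)))
            raw = sample_internal_length(params, rng)
            length = max(1, min(raw, hi - start))
            frags.append(seq[start : start + length])
    return frags


def generate_simple_decoys(seq: str, rng: np.random.Generator) -> list[str]:
    """The two cheap decoys of a SEED sequence.

    Decoy 1 permutes the sequence's non-overlapping 2-mers (an odd
    trailing residue stays last); decoy 2 is the reversed sequence.
    """
    if len(seq) < 2:
        raise ValueError("sequence too short for decoy generation")
    pairs = [seq[i : i + 2] for i in range(0, len(seq) - len(seq) % 2, 2)]
    order = rng.permutation(len(pairs))
    shuffled = "".join(pairs[i] for i in order)
    if len(seq) % 2:
        shuffled += seq[-1]
    return [shuffled, seq[::-1]]


@dataclass
class MarkovDecoyModel:
    """Order-3 Markov model over amino acids with pseudo-counts.

    The emission over the 160,000 4-tuples is
    ``(n·W + 1) / (160000 + N·W)`` (n = tuple count in the SEED, N = total
    tuple occurrences, W ≥ 1 the adaptive weight multiplying the raw
    counts — at W = 1 this is the plain pseudo-count estimate
    ``(n+1)/(160000+N)``); the distribution sums to one by construction.
    Sequences are sampled as a stationary chain: the first three residues
    from the marginal 3-prefix distribution, then next-residue
    conditionals.
    """

    counts: np.ndarray  # (20, 20, 20, 20)
    N: int
    W: float
    emission: np.ndarray = field(repr=False, default=None)
    _cum_cond: np.ndarray = field(repr=False, default=None)
    _cum_prefix: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        raw = (self.counts * self.W + 1.0) / (_TUPLE_SPACE + self.N * self.W)
        self.emission = raw / raw.sum()  # exact up to float round-off
        cond = self.emission / self.emission.sum(axis=3, keepdims=True)
        self._cum_cond = np.cumsum(cond, axis=3)
        prefix = self.emission.sum(axis=3).ravel()
        self._cum_prefix = np.cumsum(prefix / prefix.sum())

    def sample(self, length: int, rng: np.random.Generator) -> str:
        if length < 1:
            raise ValueError("length must be positive")
        u = rng.random()
        flat = int(np.searchsorted(self._cum_prefix, u, side="right"))
        flat = min(flat, _N_AA**3 - 1)
        i, rem = divmod(flat, _N_AA * _N_AA)
        j, k = divmod(rem, _N_AA)
        out = [i, j, k]
        for _ in range(3, length):
            row = self._cum_cond[out[-3], out[-2], out[-1]]
            nxt = int(np.searchsorted(row, rng.random(), side="right"))
            out.append(min(nxt, _N_AA - 1))
        return "".join(ALPHABET[x] for x in out[:length])


def fit_markov3(seed_seqs: Sequence[str], W: float = 1.0) -> MarkovDecoyModel:
    """Count overlapping 4-tuples of the SEED sequences and build the model.

    Sequences shorter than 4 residues contribute no counts; with no counts
    at all the emission is uniform over the 4-tuple space.  Tuples
    containing non-standard residues are skipped.
    """
    if not seed_seqs:
        raise ValueError("need at least one SEED sequence")
    if W < 1:
        raise ValueError("W must be >= 1")
    counts = np.zeros((_N_AA,) * 4)
    total = 0
    for seq in seed_seqs:
        idx = [_AA_INDEX.get(ch) for ch in seq.upper()]
        for a, b, c, d in zip(idx, idx[1:], idx[2:], idx[3:]):
            if None in (a, b, c, d):
                continue
            counts[a, b, c, d] += 1
            total += 1
    return MarkovDecoyModel(counts=counts, N=total, W=float(W))


class CalibrationError(RuntimeError):
    pass


def calibrate_markov_weight(
    seed_seqs: Sequence[str],
    scm: DomainModel,
    rng: np.random.Generator,
    W0: int = 10,
    decoy_len_sampler: Optional[Callable[[np.random.Generator], int]] = None,
    batch: int = 10000,
    max_W: int = 200,
    accept_range: tuple[int, int] = (1, 10),
) -> tuple[int, int]:
    """Find the smallest weight W ≥ W0 whose decoy batch is accepted at
    the target rate by the SCM (positive bit-score on 1–10 of ``batch``
    decoys).  Returns (W, accepted count); raises
    :class:`CalibrationError` if no W ≤ max_W achieves the rate.
    """
    if decoy_len_sampler is None:
        lens = [len(s) for s in seed_seqs]
        decoy_len_sampler = lambda g: int(lens[g.integers(len(lens))])
    lo, hi = accept_range
    last = -1
    for W in range(W0, max_W + 1):
        model = fit_markov3(seed_seqs, W=W)
        accepted = 0
        for _ in range(batch):
            decoy = model.sample(decoy_len_sampler(rng), rng)
            if scan_model(scm, SeqRecord(id="decoy", seq=decoy)):
                accepted += 1
        last = accepted
        if lo <= accepted <= hi:
            return W, accepted
    raise CalibrationError(
        f"no weight in [{W0}, {max_W}] reached {lo}-{hi} accepted per {batch} "
        f"decoys (last rate: {last})"
    )


@dataclass(frozen=True)
class NegativePlan:
    required: int
    deficit: int
    decoy_budget: int


#: Expected false-positive rates per decoy: midpoints of the 1–10 per
#: 10,000 (SCM) and per 1,000 (CCM) acceptance ranges.
DEFAULT_FP_RATE = {"SCM": 5e-4, "CCM": 5e-3}


def plan_negative_generation(
    n_pos: int,
    n_simple_negs: int = 0,
    model_type: str = "SCM",
    fp_rate_per_decoy: Optional[float] = None,
) -> NegativePlan:
    """Size the negative-generation effort for a domain.

    The target is a training set of roughly half negatives: ``required``
    = ceil(0.5·n_pos).  What the cheap decoys (2-mer shuffle, reversal)
    did not supply is the ``deficit`` routed to the Markov generator, and
    ``decoy_budget`` estimates how many Markov decoys must be drawn to
    harvest that many accepted negatives at the expected acceptance rate.
    """
    if n_pos < 1:
        raise ValueError("n_pos must be >= 1")
    if fp_rate_per_decoy is None:
        fp_rate_per_decoy = DEFAULT_FP_RATE[model_type]
    required = math.ceil(0.5 * n_pos)
    deficit = max(0, required - n_simple_negs)
    budget = math.ceil(deficit / fp_rate_per_decoy) if deficit else 0
    return NegativePlan(required=required, deficit=deficit, decoy_budget=budget)


def calibrate_ccm_thresholds(
    ccms: Iterable[DomainModel],
    rng: np.random.Generator,
    n: int = 1000,
    percentile: float = 99.0,
) -> dict[str, float]:
    """Bit-score surrogate for the CCM "E-value < 1" acceptance rule.

    The toy scanner emits no E-values, so each CCM gets a once-computed
    acceptance threshold: the given percentile of its best bit-scores on
    ``n`` uniform-random sequences of the model's own length.
    """
    thresholds: dict[str, float] = {}
    for ccm in sorted(ccms, key=lambda m: m.model_id):
        length = len(ccm.consensus)
        best = np.zeros(n)
        for i in range(n):
            seq = "".join(ALPHABET[j] for j in rng.integers(_N_AA, size=length))
            hits = scan_model(ccm, SeqRecord(id="rnd", seq=seq))
            if hits:
                best[i] = max(h.bit_score for h in hits)
        thresholds[ccm.model_id] = float(np.percentile(best, percentile))
    return thresholds


def screen_decoy(
    decoy: str,
    scm: Optional[DomainModel],
    ccms: Sequence[DomainModel],
    domain_acc: str,
    ccm_thresholds: Optional[dict[str, float]] = None,
) -> list[TrainingInstance]:
    """Test one decoy against the domain's models; matched decoys become
    negative training points.

    An SCM acceptance requires a positive bit-score; a CCM acceptance
    requires the hit to clear the model's calibrated threshold (the
    operational analogue of E-value < 1).  When several CCMs accept, only
    the best-scoring one contributes an instance.
    """
    out: list[TrainingInstance] = []
    rec = SeqRecord(id="decoy", seq=decoy)
    if scm is not None:
        hits = scan_model(scm, rec)
        if hits:
            best = max(hits, key=lambda h: h.bit_score)
            out.append(
                TrainingInstance(best.bit_score, best.mean_bit_score, "negative", "SCM", domain_acc)
            )
    best_ccm: Optional[DomainHit] = None
    for ccm in ccms:
        thr = (ccm_thresholds or {}).get(ccm.model_id, 0.0)
        for hit in scan_model(ccm, rec):
            if hit.bit_score > thr and (best_ccm is None or hit.bit_score > best_ccm.bit_score):
                best_ccm = hit
    if best_ccm is not None:
        out.append(
            TrainingInstance(
                best_ccm.bit_score, best_ccm.mean_bit_score, "negative", "CCM", domain_acc
            )
        )
    return out


def select_negatives(instances: Sequence[TrainingInstance], n_pos: int) -> list[TrainingInstance]:
    """Retain the strongest negatives.

    Exact duplicate (bit, mean-bit) points keep one representative; the
    rest are sorted by Euclidean distance from the origin of the score
    plane, descending, and capped at ``n_pos``.
    """
    seen: set[tuple[float, float]] = set()
    unique: list[TrainingInstance] = []
    for inst in instances:
        key = (inst.bit_score, inst.mean_bit_score)
        if key not in seen:
            seen.add(key)
            unique.append(inst)
    unique.sort(key=lambda t: (-t.distance, -t.bit_score))
    return unique[: max(0, n_pos)]


def _dedup(instances: Iterable[TrainingInstance]) -> list[TrainingInstance]:
    seen: set[tuple[float, float]] = set()
    out = []
    for inst in instances:
        key = (inst.bit_score, inst.mean_bit_score)
        if key not in seen:
            seen.add(key)
            out.append(inst)
    return out


class UnlearnableDomainError(RuntimeError):
    pass


def build_training_set(
    seed_alignment: Sequence[str],
    scm: Optional[DomainModel],
    ccms: Sequence[DomainModel],
    domain_acc: str,
    rng: np.random.Generator,
    params: FragmentParams = FragmentParams(),
    markov_W: float = 1.0,
    markov_budget: int = 2000,
    markov_batch: int = 200,
    ccm_calibration_n: int = 200,
) -> list[TrainingInstance]:
    """End-to-end training-set construction for one domain.

    Every (degapped) SEED sequence is fragmented; each fragment's best hit
    per model class yields a positive instance.  Negatives come from the
    cheap decoys first; if fewer than half the positive count, Markov
    decoys are drawn (in batches, up to ``markov_budget``) until the
    balance is reached, then the strongest negatives are selected.
    Positives are deduplicated by (bit, mean-bit) like negatives.
    """
    seqs = [row.replace("-", "").replace(".", "").upper() for row in seed_alignment]
    seqs = [s for s in seqs if len(s) >= 2]
    if not seqs:
        raise UnlearnableDomainError(f"{domain_acc}: no usable SEED sequences")

    ccm_thr = calibrate_ccm_thresholds(ccms, rng, n=ccm_calibration_n) if ccms else {}

    positives: list[TrainingInstance] = []
    for seq in seqs:
        for frag in generate_positive_fragments(seq, params, rng):
            rec = SeqRecord(id="frag", seq=frag)
            if scm is not None:
                hits = scan_model(scm, rec)
                if hits:
                    best = max(hits, key=lambda h: h.bit_score)
                    positives.append(
                        TrainingInstance(
                            best.bit_score, best.mean_bit_score, "positive", "SCM", domain_acc
                        )
                    )
            best_ccm = None
            for ccm in ccms:
                for hit in scan_model(ccm, rec):
                    if best_ccm is None or hit.bit_score > best_ccm.bit_score:
                        best_ccm = hit
            if best_ccm is not None:
                positives.append(
                    TrainingInstance(
                        best_ccm.bit_score, best_ccm.mean_bit_score, "positive", "CCM", domain_acc
                    )
                )
    by_type: dict[str, list[TrainingInstance]] = {"SCM": [], "CCM": []}
    for inst in positives:
        by_type[inst.model_type].append(inst)
    pos = {t: _dedup(v) for t, v in by_type.items()}
    if not pos["SCM"] and not pos["CCM"]:
        raise UnlearnableDomainError(f"{domain_acc}: no positive instance recoverable")

    negatives: dict[str, list[TrainingInstance]] = {"SCM": [], "CCM": []}
    for seq in seqs:
        for decoy in generate_simple_decoys(seq, rng):
            for inst in screen_decoy(decoy, scm, ccms, domain_acc, ccm_thr):
                negatives[inst.model_type].append(inst)

    required = {t: plan_negative_generation(len(pos[t])).required if pos[t] else 0 for t in pos}
    if any(len(_dedup(negatives[t])) < required[t] for t in required):
        markov = fit_markov3(seqs, W=markov_W)
        lens = [len(s) for s in seqs]
        drawn = 0
        while drawn < markov_budget and any(
            len(_dedup(negatives[t])) < required[t] for t in required
        ):
            for _ in range(min(markov_batch, markov_budget - drawn)):
                decoy = markov.sample(int(lens[rng.integers(len(lens))]), rng)
                for inst in screen_decoy(decoy, scm, ccms, domain_acc, ccm_thr):
                    negatives[inst.model_type].append(inst)
                drawn += 1

    out: list[TrainingInstance] = []
    for t in ("SCM", "CCM"):
        if not pos[t]:
            continue
        out.extend(pos[t])
        out.extend(select_negatives(negatives[t], len(pos[t])))
    return out


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

INSTANCE_COLUMNS = ["domain_acc", "model_type", "bit_score", "mean_bit_score", "label"]


def save_instances(instances: Iterable[TrainingInstance], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(INSTANCE_COLUMNS)
        for t in instances:
            writer.writerow([t.domain_acc, t.model_type, repr(t.bit_score), repr(t.mean_bit_score), t.label])


def load_instances(path: str | Path) -> list[TrainingInstance]:
    out: list[TrainingInstance] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != INSTANCE_COLUMNS:
            raise ValueError(f"unexpected training-instance header in {path}")
        for acc, mtype, bit, mbit, label in reader:
            out.append(TrainingInstance(float(bit), float(mbit), label, mtype, acc))
    return out
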