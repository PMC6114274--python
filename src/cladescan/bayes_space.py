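"""The discrete naive-Bayes probability space over (bit, mean-bit).

For each (domain, model class) pair one space is fitted: supervised
MDL discretization (Fayyad–Irani) of each score axis, Laplace-smoothed
conditional bin probabilities per class, empirical class priors, and the
bit-score lower bound — the smallest bit-score among the negative
training points.  Together these form the domain's two-dimensional
gathering threshold: a hit is accepted downstream when its bit-score
exceeds the lower bound and its posterior probability of being a true
positive exceeds the configured cut.

CCM instances of all clade models of a domain are pooled into a single
space; the SCM space is fitted separately, since bit-scores of the two
engines are not directly comparable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from cladescan.training_set import TrainingInstance

FORMAT_VERSION = 1


def _entropy(n_by_class: Sequence[int]) -> float:
    total = sum(n_by_class)
    if total == 0:
        return 0.0
    ent = 0.0
    for n in n_by_class:
        if n:
            p = n / total
            ent -= p * math.log2(p)
    return ent


def _mdl_cuts(values: np.ndarray, labels: np.ndarray) -> list[float]:
    """Recursive Fayyad–Irani MDL partitioning; returns interior cut-points."""
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]
    classes = sorted(set(labels.tolist()))

    def class_counts(yy) -> list[int]:
        return [int(np.sum(yy == c)) for c in classes]

    def recurse(vv: np.ndarray, yy: np.ndarray, out: list[float]) -> None:
        n = len(vv)
        if n < 2:
            return
        counts = class_counts(yy)
        ent = _entropy(counts)
        k = sum(1 for c in counts if c)
        if ent == 0.0:
            return
        best_gain, best_i, best_cut = -1.0, -1, 0.0
        best_parts = None
        # candidate cuts: midpoints between adjacent distinct values
        left = np.zeros(len(classes))
        for i in range(1, n):
            left[classes.index(yy[i - 1])] += 1
            if vv[i] == vv[i - 1]:
                continue
            right = np.array(counts, dtype=float) - left
            e1, e2 = _entropy(left), _entropy(right)
            gain = ent - (i / n) * e1 - ((n - i) / n) * e2
            if gain > best_gain:
                best_gain, best_i = gain, i
                best_cut = (vv[i] + vv[i - 1]) / 2.0
                best_parts = (e1, e2, int(np.sum(left > 0)), int(np.sum(right > 0)))
        if best_i < 0:
            return
        e1, e2, k1, k2 = best_parts
        delta = math.log2(3**k - 2) - (k * ent - k1 * e1 - k2 * e2)
        if best_gain <= (math.log2(n - 1) + delta) / n:
            return
        recurse(vv[:best_i], yy[:best_i], out)
        out.append(best_cut)
        recurse(vv[best_i:], yy[best_i:], out)

    cuts: list[float] = []
    recurse(v, y, cuts)
    return sorted(cuts)


def discretize(values: Sequence[float], labels: Sequence[str], fallback_bins: int = 20) -> list[float]:
    """Supervised cut-points for one score axis.

    MDL (Fayyad–Irani) cuts when the criterion accepts at least one;
    otherwise ``fallback_bins`` equal-width bins over the observed range
    (a constant axis collapses to a single interior bin).  The two
    open-ended boundary bins below/above the cut range always exist.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if len(v) < 2:
        raise ValueError("need at least 2 values to discretize")
    cuts = _mdl_cuts(v, y)
    if not cuts:
        lo, hi = float(v.min()), float(v.max())
        if hi > lo:
            cuts = list(np.linspace(lo, hi, fallback_bins + 1))
        else:
            cuts = [lo]
    # strictly increasing
    out: list[float] = []
    for c in cuts:
        if not out or c > out[-1]:
            out.append(float(c))
    return out


@dataclass
class ProbabilitySpace:
    """Fitted gathering threshold for one (domain, model class)."""

    domain_acc: str
    model_type: str
    bit_bins: list[float]
    mbit_bins: list[float]
    class_priors: dict[str, float]
    cond_probs: dict[str, dict[str, list[float]]]  # feature -> class -> per-bin P
    min_neg_bit: float
    n_pos: int
    n_neg: int
    alpha: float = 1.0

    def bin_of(self, feature: str, value: float) -> int:
        cuts = self.bit_bins if feature == "bit" else self.mbit_bins
        return int(np.searchsorted(cuts, value, side="left"))


def fit_space(
    instances: Sequence[TrainingInstance],
    alpha: float = 1.0,
) -> ProbabilitySpace:
    """Fit the discrete naive-Bayes space from labelled score points.

    Requires at least one positive and one negative instance; all
    instances must share (domain_acc, model_type).  Bin counts receive
    Laplace smoothing with parameter ``alpha``.
    """
    if not instances:
        raise ValueError("no training instances")
    accs = {(t.domain_acc, t.model_type) for t in instances}
    if len(accs) != 1:
        raise ValueError(f"instances mix several (domain, model_type) pairs: {sorted(accs)}")
    domain_acc, model_type = next(iter(accs))
    labels = [t.label for t in instances]
    n_pos = labels.count("positive")
    n_neg = labels.count("negative")
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"{domain_acc}/{model_type}: single-class training set "
            f"({n_pos} positive, {n_neg} negative) — unlearnable"
        )
    bits = [t.bit_score for t in instances]
    mbits = [t.mean_bit_score for t in instances]
    bit_bins = discretize(bits, labels)
    mbit_bins = discretize(mbits, labels)

    def cond_table(values: list[float], cuts: list[float]) -> dict[str, list[float]]:
        nbins = len(cuts) + 1
        table: dict[str, list[float]] = {}
        for cls in ("positive", "negative"):
            counts = np.full(nbins, 0.0)
            for v, lab in zip(values, labels):
                if lab == cls:
                    counts[int(np.searchsorted(cuts, v, side="left"))] += 1
            n_cls = counts.sum()
            table[cls] = list((counts + alpha) / (n_cls + alpha * nbins))
        return table

    space = ProbabilitySpace(
        domain_acc=domain_acc,
        model_type=model_type,
        bit_bins=bit_bins,
        mbit_bins=mbit_bins,
        class_priors={"positive": n_pos / len(instances), "negative": n_neg / len(instances)},
        cond_probs={"bit": cond_table(bits, bit_bins), "mbit": cond_table(mbits, mbit_bins)},
        min_neg_bit=min(t.bit_score for t in instances if t.label == "negative"),
        n_pos=n_pos,
        n_neg=n_neg,
        alpha=alpha,
    )
    return space


def posterior(space: ProbabilitySpace, bit: float, mbit: float) -> float:
    """P(positive | bit, mean-bit) under the fitted space.

    Values outside the observed range fall in the open boundary bins, so
    the posterior is defined everywhere in the plane.
    """
    b = space.bin_of("bit", bit)
    m = space.bin_of("mbit", mbit)
    num = {}
    for cls in ("positive", "negative"):
        num[cls] = (
            space.class_priors[cls]
            * space.cond_probs["bit"][cls][b]
            * space.cond_probs["mbit"][cls][m]
        )
    total = num["positive"] + num["negative"]
    return num["positive"] / total if total > 0 else 0.5


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_spaces(spaces: Iterable[ProbabilitySpace], path: str | Path) -> None:
    """Persist the gathering-threshold store (JSON, versioned)."""
    payload = {
        "format": "cladescan-ga",
        "version": FORMAT_VERSION,
        "spaces": [
            {
                "domain_acc": s.domain_acc,
                "model_type": s.model_type,
                "bit_bins": s.bit_bins,
                "mbit_bins": s.mbit_bins,
                "class_priors": s.class_priors,
                "cond_probs": s.cond_probs,
                "min_neg_bit": s.min_neg_bit,
                "n_pos": s.n_pos,
                "n_neg": s.n_neg,
                "alpha": s.alpha,
            }
            for s in spaces
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_spaces(path: str | Path) -> dict[tuple[str, str], ProbabilitySpace]:
    """Load the store as a {(domain_acc, model_type): space} mapping."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "cladescan-ga":
        raise ValueError(f"{path} is not a gathering-threshold store")
    if payload.get("version") != FORMAT_VERSION:
        raise ValueError(
            f"{path}: store version {payload.get('version')} != supported {FORMAT_VERSION}"
        )
    out: dict[tuple[str, str], ProbabilitySpace] = {}
    for rec in payload["spaces"]:
        space = ProbabilitySpace(**rec)
        out[(space.domain_acc, space.model_type)] = space
    return out
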