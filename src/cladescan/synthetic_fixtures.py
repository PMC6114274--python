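"""Synthetic domain families, model libraries and read sets.

The generator emulates the study conditions of the pipeline's target
setting: protein families with a curated SEED alignment, clade-specific
sub-families drifted from the global consensus (the niches that
clade-centered models capture), and short amino-acid reads (~60 aa,
i.e. ~180 bp ORFs) carrying planted domain fragments inside uniform
random background.  Everything is reproducible from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from cladescan.model_library import DomainModel, ModelLibrary
from cladescan.search_backend import ALPHABET, build_pssm
from cladescan.seqio import SeqRecord

_N_AA = 20


@dataclass
class SyntheticFamily:
    """One synthetic domain family with optional clade sub-families."""

    domain_acc: str
    consensus: str
    seed_alignment: list[str]
    clade_variants: dict[str, dict] = field(default_factory=dict)
    # clade -> {"variant": str, "sub_seed": [str, ...], "rate": float}

    def all_seed_rows(self) -> list[str]:
        """Global SEED rows plus every clade sub-SEED (same column count)."""
        rows = list(self.seed_alignment)
        for entry in self.clade_variants.values():
            rows.extend(entry["sub_seed"])
        return rows


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(_N_AA, size=length))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``rate``
    (always to a different residue, so ``rate`` is the realised divergence
    in expectation)."""
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        old = out[i]
        choices = [c for c in ALPHABET if c != old]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def make_family(
    rng: np.random.Generator,
    length: int = 120,
    n_seed: int = 8,
    n_clades: int = 3,
    seed_rate: float = 0.15,
    clade_rate: float = 0.35,
    clade_seed_rate: float = 0.10,
    n_clade_seed: int = 4,
    domain_acc: Optional[str] = None,
) -> SyntheticFamily:
    """Generate one family: consensus, SEED rows, clade variants.

    SEED rows diverge from the uniform-random consensus at ``seed_rate``;
    each clade variant drifts at ``clade_rate`` (default 0.35, divergent
    enough that its own model beats the consensus model on its fragments)
    and spawns a sub-SEED at ``clade_seed_rate`` around the variant.
    """
    if length < 15:
        raise ValueError("family length must be >= 15")
    for r in (seed_rate, clade_rate, clade_seed_rate):
        if not (0 <= r < 1):
            raise ValueError("rates must be in [0, 1)")
    consensus = _random_seq(rng, length)
    acc = domain_acc or f"SF{rng.integers(10_000, 99_999)}"
    seed = [mutate(consensus, seed_rate, rng) for _ in range(n_seed)]
    clades: dict[str, dict] = {}
    for c in range(n_clades):
        variant = mutate(consensus, clade_rate, rng)
        clades[f"clade{c + 1}"] = {
            "variant": variant,
            "sub_seed": [mutate(variant, clade_seed_rate, rng) for _ in range(n_clade_seed)],
            "rate": clade_rate,
        }
    return SyntheticFamily(
        domain_acc=acc, consensus=consensus, seed_alignment=seed, clade_variants=clades
    )


def make_library(families: Sequence[SyntheticFamily], pseudocount: float = 1.0) -> ModelLibrary:
    """Build the model library: one SCM per family from the full SEED and
    one CCM per clade variant from its sub-SEED."""
    if not families:
        raise ValueError("need at least one family")
    lib = ModelLibrary()
    for fam in families:
        scm_profile = build_pssm(fam.seed_alignment, pseudocount)
        lib.add(
            DomainModel(
                model_id=f"{fam.domain_acc}_SCM",
                domain_acc=fam.domain_acc,
                model_type="SCM",
                clade="",
                consensus=scm_profile.consensus,
                profile_ref=scm_profile,
            )
        )
        for clade in sorted(fam.clade_variants):
            entry = fam.clade_variants[clade]
            rows = entry["sub_seed"] if len(entry["sub_seed"]) >= 2 else entry["sub_seed"] * 2
            profile = build_pssm(rows, pseudocount)
            lib.add(
                DomainModel(
                    model_id=f"{fam.domain_acc}_{clade}",
                    domain_acc=fam.domain_acc,
                    model_type="CCM",
                    clade=clade,
                    consensus=profile.consensus,
                    profile_ref=profile,
                )
            )
    return lib


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one planted domain fragment."""

    read_id: str
    domain_acc: str
    start: int  # 1-based inclusive on the read
    end: int
    clade: str  # "" when the fragment comes from the global consensus


def make_read_set(
    families: Sequence[SyntheticFamily],
    rng: np.random.Generator,
    n_reads: int = 2000,
    read_len: int = 60,
    planted_frac: float = 0.5,
    frag_len: tuple[int, int] = (25, 55),
    noise_rate: float = 0.05,
) -> tuple[list[SeqRecord], list[PlantedTruth]]:
    """Simulate short reads with planted domain fragments.

    A planted read embeds a contiguous fragment of a family sequence
    (the global consensus or one clade variant, chosen uniformly) with
    i.i.d. substitution noise, inside uniform-random background; the
    remaining reads are pure background.  Fragment lengths are uniform in
    ``frag_len`` (clipped to the read and source lengths).
    """
    if frag_len[0] > read_len:
        raise ValueError("fragments cannot exceed the read length")
    reads: list[SeqRecord] = []
    truths: list[PlantedTruth] = []
    n_planted = int(round(planted_frac * n_reads))
    for i in range(n_reads):
        rid = f"read{i:05d}"
        if i < n_planted:
            fam = families[rng.integers(len(families))]
            sources = [("", fam.consensus)] + [
                (c, fam.clade_variants[c]["variant"]) for c in sorted(fam.clade_variants)
            ]
            clade, source = sources[rng.integers(len(sources))]
            fl = int(rng.integers(frag_len[0], frag_len[1] + 1))
            fl = min(fl, read_len, len(source))
            src_start = int(rng.integers(0, len(source) - fl + 1))
            frag = mutate(source[src_start : src_start + fl], noise_rate, rng)
            offset = int(rng.integers(0, read_len - fl + 1))
            bg = _random_seq(rng, read_len)
            seq = bg[:offset] + frag + bg[offset + fl :]
            reads.append(SeqRecord(id=rid, seq=seq))
            truths.append(
                PlantedTruth(
                    read_id=rid,
                    domain_acc=fam.domain_acc,
                    start=offset + 1,
                    end=offset + fl,
                    clade=clade,
                )
            )
        else:
            reads.append(SeqRecord(id=rid, seq=_random_seq(rng, read_len)))
    return reads, truths


def default_fixture(seed: int = 0, n_families: int = 20, n_reads: int = 2000):
    """The package's standard synthetic benchmark.

    20 families of length 80–300 aa with 3 clades each, and 2,000 reads
    of 60 aa (≈180 bp ORFs, the short-read regime the pipeline targets),
    half of them carrying a planted fragment.
    Returns (families, library, reads, truths).
    """
    rng = np.random.default_rng(seed)
    families = [
        make_family(rng, length=int(rng.integers(80, 301)), domain_acc=f"SF{i:05d}")
        for i in range(n_families)
    ]
    lib = make_library(families)
    reads, truths = make_read_set(families, rng, n_reads=n_reads)
    return families, lib, reads, truths
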