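import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladescan.hit_selection import (
    SelectionParams,
    annotate_read,
    combine_annotations,
    filter1_dedupe_same_domain,
    filter2_probability,
    filter3_rank_resolve,
)
from cladescan.search_backend import DomainHit
from cladescan.seqio import ReadAnnotation, SeqRecord


def make_hit(
    start,
    end,
    bit,
    domain="PF1",
    model="m1",
    mtype="SCM",
    identity=100.0,
    post=None,
):
    return DomainHit(
        read_id="r1",
        model_id=model,
        domain_acc=domain,
        model_type=mtype,
        ali_start=start,
        ali_end=end,
        bit_score=bit,
        mean_bit_score=bit / (end - start + 1),
        identity_pct=identity,
        posterior=post,
    )


class TestFilter1:
    def test_85pct_overlap_keeps_best(self):
        # 1-100 (bit 50) vs 10-100 (bit 40): overlap 91 covers 0.91 and 1.0
        hits = [make_hit(1, 100, 50.0, model="m1"), make_hit(10, 100, 40.0, model="m2")]
        out = filter1_dedupe_same_domain(hits)
        assert [h.bit_score for h in out] == [50.0]

    def test_two_occurrences_both_kept(self):
        # overlap 21/100 < 0.85: two occurrences of the same domain allowed
        hits = [make_hit(1, 100, 50.0, model="m1"), make_hit(80, 180, 40.0, model="m2")]
        out = filter1_dedupe_same_domain(hits)
        assert len(out) == 2

    def test_different_domains_never_interact(self):
        hits = [
            make_hit(1, 100, 50.0, domain="PF1"),
            make_hit(1, 100, 40.0, domain="PF2", model="m2"),
        ]
        assert len(filter1_dedupe_same_domain(hits)) == 2

    def test_ccm_and_scm_partitions_independent(self):
        hits = [
            make_hit(1, 100, 50.0, mtype="SCM"),
            make_hit(1, 100, 40.0, mtype="CCM", model="m2"),
        ]
        assert len(filter1_dedupe_same_domain(hits)) == 2

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_idempotent_and_no_redundant_pair(self, data):
        g = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        n = data.draw(st.integers(0, 12))
        hits = []
        for i in range(n):
            s = int(g.integers(1, 80))
            e = s + int(g.integers(5, 60))
            hits.append(
                make_hit(
                    s,
                    e,
                    float(g.uniform(1, 100)),
                    domain=f"PF{g.integers(1, 3)}",
                    model=f"m{i}",
                    mtype=("SCM", "CCM")[int(g.integers(2))],
                )
            )
        params = SelectionParams()
        once = filter1_dedupe_same_domain(hits, params)
        twice = filter1_dedupe_same_domain(once, params)
        assert twice == once
        for a, b in itertools.combinations(once, 2):
            if (a.domain_acc, a.model_type) != (b.domain_acc, b.model_type):
                continue
            ov = a.overlap(b)
            assert not (ov >= 0.85 * a.length and ov >= 0.85 * b.length)

    def test_never_increases_count(self):
        hits = [make_hit(1, 50, float(b), model=f"m{b}") for b in range(1, 6)]
        assert len(filter1_dedupe_same_domain(hits)) <= len(hits)


class FakeSpace:
    """Minimal stand-in exposing the fields filter 2 consumes."""

    def __init__(self, min_neg_bit, post):
        self.min_neg_bit = min_neg_bit
        self._post = post
        self.bit_bins = [min_neg_bit]
        self.mbit_bins = [0.0]
        self.class_priors = {"positive": 0.5, "negative": 0.5}
        # constant conditionals: posterior == post everywhere
        self.cond_probs = {
            "bit": {"positive": [post, post], "negative": [1 - post, 1 - post]},
            "mbit": {"positive": [0.5, 0.5], "negative": [0.5, 0.5]},
        }

    def bin_of(self, feature, value):
        return 0


class TestFilter2:
    def test_keeps_confident_above_floor(self):
        spaces = {("PF1", "SCM"): FakeSpace(10.0, 0.95)}
        out = filter2_probability([make_hit(1, 30, 20.0)], spaces)
        assert len(out) == 1
        assert out[0].posterior == pytest.approx(0.95)

    def test_posterior_at_most_threshold_dropped(self):
        spaces = {("PF1", "SCM"): FakeSpace(10.0, 0.89)}
        assert filter2_probability([make_hit(1, 30, 20.0)], spaces) == []

    def test_bit_equal_to_floor_dropped(self):
        spaces = {("PF1", "SCM"): FakeSpace(20.0, 0.99)}
        assert filter2_probability([make_hit(1, 30, 20.0)], spaces) == []

    def test_missing_space_drops_hit(self):
        out = filter2_probability([make_hit(1, 30, 20.0, domain="PFX")], {})
        assert out == []

    def test_085_variant_honoured(self):
        spaces = {("PF1", "SCM"): FakeSpace(10.0, 0.87)}
        params = SelectionParams(prob_threshold=0.85)
        assert len(filter2_probability([make_hit(1, 30, 20.0)], spaces, params)) == 1


def greedy_oracle(hits, shared=10):
    """Independent greedy resolver used as the reference."""
    ranked = sorted(
        hits,
        key=lambda h: (-(h.posterior * h.identity_pct / 100.0), -h.bit_score, h.model_id),
    )
    kept = []
    for h in ranked:
        if all(
            max(0, min(h.ali_end, k.ali_end) - max(h.ali_start, k.ali_start) + 1) < shared
            for k in kept
        ):
            kept.append(h)
    return sorted(kept, key=lambda h: (h.ali_start, h.ali_end, h.model_id))


class TestFilter3:
    def test_sharing_12_residues_keeps_better_rank(self):
        h1 = make_hit(1, 30, 50.0, model="m1", post=0.90)
        h2 = make_hit(19, 48, 60.0, model="m2", domain="PF2", post=0.80)
        out = filter3_rank_resolve([h1, h2])
        assert [h.model_id for h in out] == ["m1"]

    def test_sharing_9_residues_both_kept(self):
        h1 = make_hit(1, 30, 50.0, model="m1", post=0.95)
        h2 = make_hit(22, 48, 60.0, model="m2", domain="PF2", post=0.80)
        out = filter3_rank_resolve([h1, h2])
        assert len(out) == 2

    def test_single_hit_retained(self):
        out = filter3_rank_resolve([make_hit(1, 30, 50.0, post=0.99)])
        assert len(out) == 1
        assert out[0].ranking_score == pytest.approx(0.99)

    def test_ranking_uses_identity(self):
        h1 = make_hit(1, 30, 50.0, model="m1", post=0.9, identity=50.0)  # rank 0.45
        h2 = make_hit(1, 30, 40.0, model="m2", domain="PF2", post=0.8, identity=100.0)  # 0.8
        out = filter3_rank_resolve([h1, h2])
        assert out[0].ranking_score == pytest.approx(0.8)
        assert [h.model_id for h in out] == ["m2"]

    def test_requires_posterior(self):
        with pytest.raises(ValueError, match="posterior"):
            filter3_rank_resolve([make_hit(1, 30, 50.0)])

    def test_exhaustive_small_instances_match_oracle(self):
        # systematic sweep over up-to-5-hit instances on a small grid
        pool = []
        k = 0
        for start in (1, 8, 15, 24):
            for length in (10, 15):
                for post in (0.91, 0.95, 0.99):
                    k += 1
                    pool.append(
                        make_hit(
                            start,
                            start + length - 1,
                            float(20 + k),
                            domain=f"PF{k % 3}",
                            model=f"m{k:02d}",
                            post=post,
                        )
                    )
        rng = np.random.default_rng(5)
        for size in (2, 3, 4, 5):
            for _ in range(40):
                chosen = [pool[i] for i in rng.choice(len(pool), size=size, replace=False)]
                for h in chosen:
                    h.ranking_score = None
                got = filter3_rank_resolve(list(chosen))
                exp = greedy_oracle(chosen)
                assert [h.model_id for h in got] == [h.model_id for h in exp]

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_pairwise_share_at_most_9(self, data):
        g = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        hits = []
        for i in range(int(g.integers(0, 10))):
            s = int(g.integers(1, 50))
            e = s + int(g.integers(5, 40))
            hits.append(
                make_hit(s, e, float(g.uniform(1, 100)), model=f"m{i}", post=float(g.uniform(0.5, 1)))
            )
        out = filter3_rank_resolve(hits)
        for a, b in itertools.combinations(out, 2):
            assert a.overlap(b) <= 9


class TestAnnotateRead:
    def test_planted_fragment_one_hit(self, small_family, small_library, trained_small):
        _, spaces = trained_small
        frag = small_family.consensus[20:60]
        read = SeqRecord("rX", "MKVLIWAADE" + frag + "CCHHKKWWYY")
        anno = annotate_read(read, small_library, spaces)
        assert len(anno) >= 1
        best = max(anno.hits, key=lambda h: h.bit_score)
        assert best.domain_acc == small_family.domain_acc

    def test_background_read_empty(self, small_library, trained_small, rng):
        _, spaces = trained_small
        aa = "ACDEFGHIKLMNPQRSTVWY"
        read = SeqRecord("rBG", "".join(aa[i] for i in rng.integers(20, size=60)))
        anno = annotate_read(read, small_library, spaces)
        assert isinstance(anno, ReadAnnotation)
        # filters never increase hit count; an empty result is legitimate
        assert len(anno) <= 2

    def test_counters_funnel_monotone(self, small_family, small_library, trained_small):
        _, spaces = trained_small
        counters = {}
        read = SeqRecord("rX", small_family.consensus[:60])
        annotate_read(read, small_library, spaces, counters=counters)
        assert counters["raw"] >= counters["after_f1"] >= counters["after_f2"] >= counters["after_f3"]


class TestCombine:
    def _anno(self, rid, n_hits=1, tool="A"):
        hits = [make_hit(1 + 20 * i, 15 + 20 * i, 30.0, model=f"m{i}") for i in range(n_hits)]
        return ReadAnnotation(read_id=rid, hits=hits, source_tool=tool)

    def test_secondary_fills_gaps_only(self):
        primary = [self._anno("r1")]
        secondary = [self._anno("r1", tool="B"), self._anno("r2", tool="B")]
        out = combine_annotations(primary, secondary)
        by_id = {a.read_id: a for a in out}
        assert by_id["r1"].source_tool == "A"
        assert by_id["r2"].source_tool == "B"

    def test_empty_secondary(self):
        primary = [self._anno("r1")]
        assert combine_annotations(primary, []) == primary

    def test_monotone_size(self):
        primary = [self._anno("r1"), self._anno("r2")]
        secondary = [self._anno("r3", tool="B")]
        assert len(combine_annotations(primary, secondary)) >= len(primary)

    def test_duplicate_read_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            combine_annotations([self._anno("r1"), self._anno("r1")], [])

    def test_empty_primary_annotation_does_not_block(self):
        primary = [ReadAnnotation("r1", hits=[], source_tool="A")]
        secondary = [self._anno("r1", tool="B")]
        out = combine_annotations(primary, secondary)
        assert any(a.source_tool == "B" and len(a) for a in out)
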