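"""Seed-edit detection against a Hamming oracle; ratio classification."""

import pytest

from smallrna_dx import basedit as be
from smallrna_dx import profiling as pr
from smallrna_dx._util import normalize_seq


def _mutate(seq, pos_1based, new_base):
    i = pos_1based - 1
    assert seq[i] != new_base
    return seq[:i] + new_base + seq[i + 1 :]


def hamming_oracle(tag, reference):
    """Brute force: miRNAs at Hamming distance exactly 1, mismatch in seed 2-8."""
    tag = normalize_seq(tag)
    out = []
    for m in reference:
        ref = normalize_seq(m.sequence)
        if len(ref) != len(tag):
            continue
        diffs = [i + 1 for i in range(len(ref)) if ref[i] != tag[i]]
        if len(diffs) == 1 and 2 <= diffs[0] <= 8:
            out.append((m.name, diffs[0]))
    return sorted(out)


REF = [
    pr.MatureMiRNA("mA", "TAGCTTATCAGACTGATGTTGA"),  # 22 nt
    pr.MatureMiRNA("mB", "ACTGGCCTACAAAGTCCCAGT"),  # 21 nt
]


class TestFindSeedEdits:
    def test_single_seed_mismatch_detected(self):
        tag = _mutate(REF[0].sequence, 5, "C")
        hits = be.find_seed_edits(tag, REF)
        assert len(hits) == 1
        h = hits[0]
        assert (h.mirna, h.edit_position, h.ref_base, h.obs_base) == ("mA", 5, "T", "C")

    def test_mismatch_outside_seed_ignored(self):
        tag = _mutate(REF[0].sequence, 9, "G")
        assert be.find_seed_edits(tag, REF) == []

    def test_two_mismatches_ignored(self):
        tag = _mutate(_mutate(REF[0].sequence, 3, "A"), 6, "C")
        assert be.find_seed_edits(tag, REF) == []

    def test_position_boundaries(self):
        for pos, expect_hit in [(1, False), (2, True), (8, True), (9, False)]:
            base = REF[1].sequence
            new = "G" if base[pos - 1] != "G" else "A"
            hits = be.find_seed_edits(_mutate(base, pos, new), REF)
            assert bool(hits) == expect_hit, f"position {pos}"

    def test_multi_parent_flagged(self):
        twins = [
            pr.MatureMiRNA("t1", "AAAATTTTCCCCGGGGAAAA"),
            pr.MatureMiRNA("t2", "AGAATTTTCCCCGGGGAAAA"),  # differs at pos 2
        ]
        tag = _mutate(twins[0].sequence, 4, "C")  # 1 mismatch from t1, 2 from t2
        hits = be.find_seed_edits(tag, twins)
        assert [h.mirna for h in hits] == ["t1"]
        # a tag one seed-mismatch from both parents is reported for both
        tag2 = _mutate(twins[0].sequence, 2, "C")  # A->C at 2: dist1 from both
        hits2 = be.find_seed_edits(tag2, twins)
        assert sorted(h.mirna for h in hits2) == ["t1", "t2"]
        assert all(h.multi for h in hits2)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            be.find_seed_edits("ACGT", [])

    def test_randomized_against_hamming_oracle(self, rng, mature_reference):
        """Random tags (planted edits, random-length decoys) match the oracle."""
        for _ in range(300):
            draw = rng.random()
            if draw < 0.5:  # planted single seed edit
                m = mature_reference[int(rng.integers(len(mature_reference)))]
                pos = int(rng.integers(2, 9))
                old = m.sequence[pos - 1]
                new = str(rng.choice([b for b in "ACGT" if b != old]))
                tag = _mutate(m.sequence, pos, new)
            elif draw < 0.75:  # double mutant
                m = mature_reference[int(rng.integers(len(mature_reference)))]
                p1, p2 = rng.choice(range(1, len(m.sequence) + 1), 2, replace=False)
                tag = m.sequence
                for p in (int(p1), int(p2)):
                    old = tag[p - 1]
                    tag = _mutate(tag, p, str(rng.choice([b for b in "ACGT" if b != old])))
            else:  # random sequence
                tag = "".join(rng.choice(list("ACGT"), size=int(rng.integers(18, 25))))
            got = sorted((h.mirna, h.edit_position) for h in be.find_seed_edits(tag, mature_reference))
            assert got == hamming_oracle(tag, mature_reference)


class TestPercentagesAndRatios:
    @pytest.mark.parametrize(
        "edited,exact,expected",
        [(5, 5, 50.0), (0, 10, 0.0), (10, 0, 100.0)],
    )
    def test_edit_percentage(self, edited, exact, expected):
        assert be.edit_percentage(edited, exact) == expected

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            be.edit_percentage(0, 0)

    @pytest.mark.parametrize(
        "pct_mn,pct_nc,ratio,cls",
        [
            (10.64, 11.48, 0.93, "lt1"),
            (100.00, 99.55, 1.00, "eq1"),
            (25.59, 0.48, 53.31, "gt1"),
            (50.0, 50.0, 1.00, "eq1"),
        ],
    )
    def test_edit_ratio_classification(self, pct_mn, pct_nc, ratio, cls):
        got_ratio, got_cls = be.edit_ratio(pct_mn, pct_nc)
        assert (got_ratio, got_cls) == (ratio, cls)

    def test_undefined_ratio_when_control_is_zero(self):
        assert be.edit_ratio(10.0, 0.0) == (None, None)

    def test_rounded_boundary_lands_in_eq1(self):
        """Any pair whose rounded ratio is 1.00 classifies as =1."""
        ratio, cls = be.edit_ratio(100.0, 99.55)
        assert ratio == 1.00 and cls == "eq1"
        ratio, cls = be.edit_ratio(99.0, 100.0)
        assert ratio == 0.99 and cls == "lt1"


class TestPartition:
    def test_counts_partition_classified_total(self):
        summaries = [
            be.EditSummary("a", 10.0, 5.0, 2.0, "gt1"),
            be.EditSummary("b", 5.0, 5.0, 1.0, "eq1"),
            be.EditSummary("c", 1.0, 5.0, 0.2, "lt1"),
            be.EditSummary("d", 1.0, 0.0, None, None),
        ]
        gt1, eq1, lt1 = be.edit_partition(summaries)
        assert (gt1, eq1, lt1) == (1, 1, 1)
        n_classified = sum(1 for s in summaries if s.edit_class is not None)
        assert gt1 + eq1 + lt1 == n_classified

    def test_empty_input(self):
        assert be.edit_partition([]) == (0, 0, 0)

    def test_mn_only_excess_never_lands_lt1(self):
        """Planted excess edits in the disease group only: no <1 class."""
        exact = {"m1": 90, "m2": 80}
        summaries, _ = be.summarize_edits(
            exact_mn=exact, edited_mn={"m1": 10, "m2": 20},
            exact_nc=exact, edited_nc={"m1": 0, "m2": 0},
        )
        _gt1, _eq1, lt1 = be.edit_partition(summaries)
        assert lt1 == 0
        # zero NC percentage -> undefined ratio, excluded from the partition
        assert all(s.edit_class is None for s in summaries)

    def test_exactness_trumps_edit(self, mature_reference):
        """A tag equal to one mature sequence never counts as an edit of another."""
        from smallrna_dx import profiling as pr_mod

        m = mature_reference[0]
        tags = {m.sequence: 5}
        counts, unannotated = pr_mod.count_known(tags, mature_reference)
        assert counts[m.name] == 5
        assert unannotated == {}  # nothing reaches the edit stage


def test_summarize_edits_requires_presence_in_both_groups():
    summaries, skipped = be.summarize_edits(
        exact_mn={"m1": 10}, edited_mn={"m1": 2},
        exact_nc={}, edited_nc={},
    )
    assert summaries == []
    assert skipped == ["m1"]
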