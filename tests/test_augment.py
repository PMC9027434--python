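import numpy as np
import pytest

from arspawner import (
    AugmentationConfig,
    Dataset,
    TimeSeries,
    acceptance_threshold,
    augment,
    class_statistics,
    dba,
    evaluate_candidate,
)
from arspawner.dtw import WarpingPath
from arspawner.errors import DegenerateClassError
from arspawner.spawner import SpawnerCandidate
from arspawner.dba import ClassStatistics


def _diag_path(L):
    return WarpingPath(np.stack([np.arange(1, L + 1)] * 2, axis=1))


def _candidate(values, label="k", parents=("p1", "p2")):
    values = np.asarray(values, dtype=float)
    return SpawnerCandidate(
        values=values, parents=parents, label=label,
        split_fraction=0.5, split=(1, 1), path=_diag_path(values.shape[0]),
        candidate_id="cand",
    )


class TestAcceptanceThreshold:
    def test_zero_std(self):
        st = ClassStatistics("k", 10.0, 0.0, 3)
        assert acceptance_threshold(st, 0.5, 0.5) == pytest.approx(5.0)

    def test_direct_arithmetic(self):
        st = ClassStatistics("k", 10.0, 2.0, 3)
        # 0.5*10 + 2*(0.5 + 2/10) = 6.4
        assert acceptance_threshold(st, 0.5, 0.5) == pytest.approx(6.4)

    def test_monotone_in_r1_r2(self):
        st = ClassStatistics("k", 8.0, 3.0, 6)
        base = acceptance_threshold(st, 0.3, 0.3)
        assert acceptance_threshold(st, 0.6, 0.3) > base
        assert acceptance_threshold(st, 0.3, 0.6) > base

    def test_degenerate_class(self):
        with pytest.raises(DegenerateClassError):
            acceptance_threshold(ClassStatistics("k", 0.0, 0.0, 1), 0.5, 0.5)


class TestEvaluateCandidate:
    """Hand-enumerable toy: constant series at levels 0, 1, 2 (length 5).

    Pairwise distances 5, 20, 5 -> mean 10, std sqrt(50) ~ 7.071; the DBA
    representative is constant 1.  With r1 = r2 = 0.5 the bounds are
    lower = 5 and T = 5 + sqrt(50)*(0.5 + sqrt(50)/10) ~ 13.536.
    """

    @pytest.fixture
    def toy(self, constant_series):
        stats = class_statistics(constant_series)["k"]
        rep = dba(list(constant_series))
        return constant_series, stats, rep

    def test_candidate_identical_to_parent_rejected(self, toy):
        data, stats, rep = toy
        cand = _candidate(data[0].values, parents=("const-0", "const-1"))
        rep_ = evaluate_candidate(cand, data[0], rep, stats, 0.5, 0.5)
        assert not rep_.accepted
        assert "d1-lower" in rep_.failed_conditions

    def test_hand_computed_distances_and_verdict(self, toy):
        data, stats, rep = toy
        # candidate constant at 1.4: d1 (vs level 0) = 1.4^2*5 = 9.8,
        # d2 (vs rep at 1) = 0.4^2*5 = 0.8 -> fails only the d2 lower bound
        cand = _candidate(np.full((5, 1), 1.4), parents=("const-0", "const-1"))
        r = evaluate_candidate(cand, data[0], rep, stats, 0.5, 0.5)
        assert r.d1 == pytest.approx(9.8)
        assert r.d2 == pytest.approx(0.8)
        assert r.lower_bound == pytest.approx(5.0)
        assert r.upper_bound == pytest.approx(5 + np.sqrt(50) * (0.5 + np.sqrt(50) / 10))
        assert r.failed_conditions == ("d2-lower",)

    def test_in_interval_accepted(self, toy):
        data, stats, rep = toy
        # constant at 2.2: d1 = 2.2^2*5 = 24.2 vs level 0... too big; use
        # level sqrt-scaled: pick c with both d1, d2 in (5, 13.536):
        # d1 = c^2*5 (vs 0), d2 = (c-1)^2*5 (vs 1); c = -0.55 ->
        # d1 = 1.5125, no. c = 2.05: d1=21 no. Evaluate vs parent level 1:
        cand = _candidate(np.full((5, 1), 2.4), parents=("const-1", "const-2"))
        r = evaluate_candidate(cand, data[1], rep, stats, 0.5, 0.5)
        # d1 = (2.4-1)^2*5 = 9.8, d2 = (2.4-1)^2*5 = 9.8: both in (5, 13.536)
        assert r.d1 == pytest.approx(9.8) and r.d2 == pytest.approx(9.8)
        assert r.accepted

    def test_ablation_modes(self, toy):
        data, stats, rep = toy
        near = _candidate(np.full((5, 1), 1.05), parents=("const-1", "const-2"))
        # d1, d2 tiny: fails both lower bounds, passes both upper bounds
        full = evaluate_candidate(near, data[1], rep, stats, 0.5, 0.5, mode="both")
        assert set(full.failed_conditions) == {"d1-lower", "d2-lower"}
        up_only = evaluate_candidate(near, data[1], rep, stats, 0.5, 0.5, mode="upper-only")
        assert up_only.accepted
        no_d1 = evaluate_candidate(near, data[1], rep, stats, 0.5, 0.5, mode="no-d1")
        assert no_d1.failed_conditions == ("d2-lower",)
        with pytest.raises(ValueError, match="mode"):
            AugmentationConfig(mode="bogus")

    def test_class_mismatch_raises(self, toy, rng):
        data, stats, rep = toy
        other = TimeSeries(rng.normal(size=(5, 1)), "other", "s", "o")
        cand = _candidate(np.full((5, 1), 1.4))
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_candidate(cand, other, rep, stats, 0.5, 0.5)


class TestAugment:
    def test_duplicate_only_classes_accept_nothing(self, rng):
        X = rng.normal(size=(8, 2))
        data = Dataset(
            [TimeSeries(X, "k", "s", f"d{i}") for i in range(3)], name="dups"
        )
        with pytest.warns(UserWarning, match="identical"):
            augmented, reports = augment(data, AugmentationConfig(seed=0))
        assert len(augmented) == len(data)
        assert reports == []

    def test_accepted_subset_and_reports_revalidate(self, small_dataset):
        aug, reports = augment(small_dataset, AugmentationConfig(seed=11))
        generated_ids = {r.candidate_id for r in reports}
        new = [s for s in aug if s.series_id.startswith("aug:")]
        assert {s.series_id for s in new} <= generated_ids
        accepted_ids = {r.candidate_id for r in reports if r.accepted}
        assert {s.series_id for s in new} == accepted_ids
        for r in reports:
            should = (
                r.d1 > r.lower_bound and r.d2 > r.lower_bound
                and r.d1 < r.upper_bound and r.d2 < r.upper_bound
            )
            assert r.accepted == should
            assert r.accepted == (not r.failed_conditions)

    def test_inputs_untouched_and_labels_conserved(self, small_dataset):
        before = {s.series_id: s.values.copy() for s in small_dataset}
        aug, _ = augment(small_dataset, AugmentationConfig(seed=3))
        for s in small_dataset:
            assert np.array_equal(before[s.series_id], s.values)
        assert set(aug.classes) == set(small_dataset.classes)
        assert [s.series_id for s in aug[: len(small_dataset)]] == [
            s.series_id for s in small_dataset
        ]

    def test_deterministic_under_seed(self, small_dataset):
        a1, _ = augment(small_dataset, AugmentationConfig(seed=21))
        a2, _ = augment(small_dataset, AugmentationConfig(seed=21))
        assert len(a1) == len(a2)
        for s1, s2 in zip(a1, a2):
            assert np.array_equal(s1.values, s2.values)

    def test_acceptance_nested_in_r2(self, small_dataset):
        # larger r2 only raises the upper bound, so accepted sets are nested
        sets = []
        for r2 in (0.2, 0.6, 1.0):
            _, reports = augment(
                small_dataset, AugmentationConfig(r1=0.5, r2=r2, seed=8)
            )
            sets.append({r.candidate_id for r in reports if r.accepted})
        assert sets[0] <= sets[1] <= sets[2]

    def test_interval_translates_with_r1(self, small_dataset):
        # the acceptance interval has constant width in r1: both bounds
        # shift by the same amount r1 * d_mean
        _, lo_reports = augment(small_dataset, AugmentationConfig(r1=0.2, seed=8))
        _, hi_reports = augment(small_dataset, AugmentationConfig(r1=0.8, seed=8))
        for a, b in zip(lo_reports, hi_reports):
            assert (a.upper_bound - a.lower_bound) == pytest.approx(
                b.upper_bound - b.lower_bound
            )

    def test_accepted_count_bounded_by_pairs(self, small_dataset):
        _, reports = augment(small_dataset, AugmentationConfig(seed=2))
        n_pairs = sum(
            len(m) * (len(m) - 1) // 2
            for m in small_dataset.by_class().values()
        )
        assert len(reports) == n_pairs
        assert sum(r.accepted for r in reports) <= n_pairs

    def test_small_class_skipped_with_warning(self, rng):
        data = Dataset(
            [
                TimeSeries(rng.normal(size=(6, 1)), "solo", "s", "x"),
                TimeSeries(rng.normal(size=(6, 1)), "pairA", "s", "y1"),
                TimeSeries(rng.normal(size=(7, 1)), "pairA", "s", "y2"),
            ]
        )
        with pytest.warns(UserWarning, match="solo"):
            augmented, reports = augment(data, AugmentationConfig(seed=0))
        assert all(r.label == "pairA" for r in reports)
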