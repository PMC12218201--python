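import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexstrata.formats_io import DepthTrack, GenomicInterval
from sexstrata.slr_detect import (
    WindowConfig,
    build_window_table,
    call_regions,
    classify_windows,
    detect_slr,
    normalize,
    repeat_fraction,
    window_depths,
)
from sexstrata.synthetic_data import SimConfig, simulate_depth_tracks


def constant_track(depth, length, chrom="c"):
    return DepthTrack(chrom, length, [0], [length], [depth])


class TestWindowDepths:
    def test_constant_track_window_count_and_means(self):
        cfg = WindowConfig(window=50_000, step=5_000)
        t = constant_track(30, 200_000)
        df = window_depths(t, cfg)
        assert len(df) == (200_000 - 50_000) // 5_000 + 1 == 31
        assert (df["mean_depth"] == 30.0).all()

    def test_two_level_window_mean(self):
        t = DepthTrack("c", 50_000, [0, 25_000], [25_000, 50_000], [10, 30])
        cfg = WindowConfig(window=50_000, step=50_000)
        df = window_depths(t, cfg)
        assert len(df) == 1 and df["mean_depth"].iloc[0] == 20.0

    def test_short_chromosome_warns_and_empty(self):
        cfg = WindowConfig(window=50_000, step=5_000)
        with pytest.warns(UserWarning, match="shorter"):
            df = window_depths(constant_track(5, 10_000), cfg)
        assert df.empty

    def test_random_track_matches_per_base_oracle(self, rng):
        dense = rng.integers(0, 60, size=1_000_000)
        t = DepthTrack.from_dense("c", dense)
        cfg = WindowConfig(window=50_000, step=5_000)
        df = window_depths(t, cfg)
        # naive per-base recomputation on a sample of windows
        for i in rng.choice(len(df), size=25, replace=False):
            s, e = df["start"].iloc[i], df["end"].iloc[i]
            assert df["mean_depth"].iloc[i] == pytest.approx(
                dense[s:e].mean(), abs=1e-9
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        length=st.integers(min_value=1, max_value=500_000),
        window=st.integers(min_value=1, max_value=100_000),
        step_frac=st.integers(min_value=1, max_value=100),
    )
    def test_window_count_formula(self, length, window, step_frac):
        step = max(1, window * step_frac // 100)
        cfg = WindowConfig(
            window=window, step=step, min_region=1, max_gap=0,
        )
        t = constant_track(7, length)
        if length < window:
            with pytest.warns(UserWarning):
                df = window_depths(t, cfg)
            assert df.empty
        else:
            df = window_depths(t, cfg)
            assert len(df) == (length - window) // step + 1


class TestNormalize:
    def _table(self, male, female):
        n = len(male)
        return pd.DataFrame(
            {
                "chrom": "c",
                "start": np.arange(n) * 5_000,
                "end": np.arange(n) * 5_000 + 50_000,
                "male_depth": male,
                "female_depth": female,
            }
        )

    def test_identity_when_constant(self):
        t = self._table([30.0] * 10, [30.0] * 10)
        out = normalize(t)
        assert (out["male_rel"] == 1.0).all() and (out["female_rel"] == 1.0).all()
        assert out.attrs["normalizer_values"] == {"male": 30.0, "female": 30.0}

    def test_median_normalizer_odd_window(self):
        t = self._table([30.0] * 9 + [15.0], [30.0] * 10)
        out = normalize(t, "median")
        assert out["male_rel"].iloc[-1] == 0.5

    def test_zero_normalizer_raises(self):
        t = self._table([0.0] * 5, [30.0] * 5)
        with pytest.raises(ValueError, match="normalizer is zero"):
            normalize(t)

    def test_mean_vs_median_agree_on_symmetric_simulation(self, rng):
        vals = rng.poisson(30, size=2_000).astype(float)
        t = self._table(vals, vals)
        m1 = normalize(t, "mean").attrs["normalizer_values"]["male"]
        m2 = normalize(t, "median").attrs["normalizer_values"]["male"]
        assert abs(m1 - m2) / m2 < 0.01

    def test_exclude_removes_region_windows(self):
        # non-overlapping windows so the excluded region maps cleanly
        t = pd.DataFrame(
            {
                "chrom": "c",
                "start": np.arange(10) * 50_000,
                "end": (np.arange(10) + 1) * 50_000,
                "male_depth": [30.0] * 8 + [15.0, 15.0],
                "female_depth": [30.0] * 10,
            }
        )
        out = normalize(t, "mean", exclude=[GenomicInterval("c", 400_000, 500_000)])
        assert out.attrs["normalizer_values"]["male"] == 30.0


class TestClassify:
    def _row(self, male_rel, female_rel):
        df = pd.DataFrame(
            {
                "chrom": ["c"],
                "start": [0],
                "end": [50_000],
                "male_rel": [male_rel],
                "female_rel": [female_rel],
            }
        )
        return classify_windows(df, WindowConfig())["window_class"].iloc[0]

    @pytest.mark.parametrize(
        "male_rel,female_rel,expected",
        [
            (0.5, 0.02, "Y_linked"),   # half male coverage, negligible female
            (1.0, 1.0, "balanced"),
            (0.5, 1.0, "X_linked"),    # reduced male, average female
            (0.2, 0.2, "ambiguous"),
            (1.5, 1.0, "ambiguous"),
        ],
    )
    def test_examples(self, male_rel, female_rel, expected):
        assert self._row(male_rel, female_rel) == expected

    def test_classification_is_a_partition(self, rng):
        df = pd.DataFrame(
            {
                "chrom": "c",
                "start": np.arange(500) * 5_000,
                "end": np.arange(500) * 5_000 + 50_000,
                "male_rel": rng.uniform(0, 2, 500),
                "female_rel": rng.uniform(0, 2, 500),
            }
        )
        out = classify_windows(df, WindowConfig())
        assert out["window_class"].isin(
            ["Y_linked", "X_linked", "balanced", "ambiguous"]
        ).all()
        assert len(out) == 500


class TestCallRegions:
    def _labeled(self, classes, step=5_000, window=50_000):
        n = len(classes)
        return pd.DataFrame(
            {
                "chrom": "c",
                "start": np.arange(n) * step,
                "end": np.arange(n) * step + window,
                "window_class": classes,
            }
        )

    def test_no_slr_windows_gives_one_chromosome_par(self):
        cfg = WindowConfig()
        labeled = self._labeled(["balanced"] * 40)
        calls = call_regions(labeled, cfg, 245_000)
        (c,) = calls
        assert c.slr_type == "none" and c.span_bp == 0
        assert len(c.pars) == 1 and len(c.pars[0]) == 245_000

    def test_geometry_fraction_identity(self):
        cfg = WindowConfig(min_region=100_000)
        classes = ["balanced"] * 20 + ["Y_linked"] * 40 + ["balanced"] * 20
        chrom_length = 79 * 5_000 + 50_000
        calls = call_regions(self._labeled(classes), cfg, chrom_length)
        (c,) = [x for x in calls if x.slr_type == "Y"]
        assert c.span_bp == c.interval.end - c.interval.start
        assert c.span_bp + c.par_total_bp == chrom_length
        assert c.fraction_of_chromosome == pytest.approx(
            c.span_bp / (c.span_bp + c.par_total_bp)
        )

    def test_gap_bridging_and_min_region(self):
        cfg = WindowConfig(min_region=150_000, max_gap=20_000)
        classes = (
            ["balanced"] * 10
            + ["Y_linked"] * 10 + ["ambiguous"] * 3 + ["Y_linked"] * 10  # bridged
            + ["balanced"] * 30
            + ["Y_linked"] * 2  # too short, dropped
            + ["balanced"] * 10
        )
        calls = call_regions(self._labeled(classes), cfg, 500_000)
        ys = [c for c in calls if c.slr_type == "Y"]
        assert len(ys) == 1
        assert ys[0].interval.start == 10 * 5_000
        assert ys[0].interval.end == 32 * 5_000 + 50_000

    def test_overlapping_x_and_y_calls_raise(self):
        cfg = WindowConfig(min_region=50_000, max_gap=100_000)
        classes = ["Y_linked", "X_linked"] * 20
        with pytest.raises(ValueError, match="inconsistent"):
            call_regions(self._labeled(classes), cfg, 300_000)

    def test_planted_region_recovered_within_one_step(self):
        cfg = SimConfig(seed=42)
        male, female, truth = simulate_depth_tracks(cfg)
        calls, _ = detect_slr(male, female)
        (c,) = [x for x in calls if x.slr_type == "Y"]
        step = WindowConfig().step
        assert abs(c.interval.start - cfg.slr_start) <= step
        assert abs(c.interval.end - cfg.slr_end) <= step

    def test_x_linked_region_recovered(self):
        # X boundaries lack the sharp female-absence signal of a Y region:
        # an edge window >=60% inside still reads male_rel <= 0.7, so the
        # attainable precision is window*(1 - 0.6) outward plus one step in
        cfg = SimConfig(seed=42, slr_type="X")
        male, female, truth = simulate_depth_tracks(cfg)
        calls, _ = detect_slr(male, female)
        (c,) = [x for x in calls if x.slr_type == "X"]
        wcfg = WindowConfig()
        slack = int(0.4 * wcfg.window) + wcfg.step
        assert abs(c.interval.start - cfg.slr_start) <= slack
        assert abs(c.interval.end - cfg.slr_end) <= slack


class TestRepeatFraction:
    def test_full_cover(self):
        iv = GenomicInterval("c", 0, 100)
        assert repeat_fraction(iv, [GenomicInterval("c", 0, 100)]) == 1.0

    def test_overlapping_repeats_unioned(self):
        iv = GenomicInterval("c", 0, 100)
        reps = [GenomicInterval("c", 0, 30), GenomicInterval("c", 20, 60)]
        assert repeat_fraction(iv, reps) == 0.60

    def test_other_chromosome_ignored(self):
        iv = GenomicInterval("c", 0, 100)
        assert repeat_fraction(iv, [GenomicInterval("d", 0, 100)]) == 0.0

    def test_random_intervals_match_bitmap_oracle(self, rng):
        iv = GenomicInterval("c", 1_000, 11_000)
        reps = []
        bitmap = np.zeros(20_000, dtype=bool)
        for _ in range(200):
            s = int(rng.integers(0, 19_000))
            e = s + int(rng.integers(1, 800))
            reps.append(GenomicInterval("c", s, min(e, 20_000)))
            bitmap[s:min(e, 20_000)] = True
        expected = bitmap[1_000:11_000].mean()
        assert repeat_fraction(iv, reps) == pytest.approx(expected, abs=1e-12)


def test_detect_slr_window_table_is_classified(rng):
    cfg = SimConfig(seed=3, chrom_length=2_000_000, slr_start=500_000, slr_end=1_200_000)
    male, female, _ = simulate_depth_tracks(cfg)
    calls, labeled = detect_slr(male, female)
    assert "window_class" in labeled.columns
    assert labeled["window_class"].notna().all()
    inside = labeled[
        (labeled["start"] >= cfg.slr_start) & (labeled["end"] <= cfg.slr_end)
    ]
    assert (inside["window_class"] == "Y_linked").mean() > 0.95
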