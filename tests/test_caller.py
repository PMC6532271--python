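"""The local-maxima caller: smoothing, windowed maxima, geometric-mean filter."""

import numpy as np
import pandas as pd
import pytest

from chicmax import (
    CallerParams,
    Virtual4CProfile,
    build_virtual_4c,
    call_bait,
    call_dataset,
    distance_bin_geomeans,
    find_local_maxima,
    loess_smooth,
)
from chicmax.io import InteractionTable

from conftest import make_table


def brute_force_windowed_maxima(smoothed, w):
    """O(n*w) oracle: i is a maximum iff it attains the max of its window."""
    half = w // 2
    n = len(smoothed)
    out = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if smoothed[i] == max(smoothed[lo:hi]):
            out.append(i)
    return out


def manual_lowess(x, y, frac):
    """Independent degree-1 tricube lowess (k = int(frac*n) nearest points)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = int(frac * n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.sort(np.argsort(d, kind="stable")[:k])
        dmax = d[idx].max()
        w = np.clip(1 - (d[idx] / dmax) ** 3, 0, 1) ** 3 if dmax > 0 else np.ones(len(idx))
        sw = np.sqrt(w)
        X = np.vstack([np.ones(len(idx)), x[idx]]).T
        beta = np.linalg.lstsq(X * sw[:, None], y[idx] * sw, rcond=None)[0]
        out[i] = beta[0] + beta[1] * x[i]
    return out


def profile_from_arrays(positions, counts, frag=1000, bait_end=0):
    """Directly build a one-sided virtual 4C profile for caller unit tests."""
    positions = np.asarray(positions, dtype=np.float64)
    counts = np.asarray(counts, dtype=np.float64)
    starts = (positions - frag / 2).astype(np.int64)
    ends = (positions + frag / 2).astype(np.int64)
    return Virtual4CProfile(
        bait_id=0, bait_chrom="chr1", bait_start=bait_end - frag,
        bait_end=bait_end, bait_name="bait_0",
        oe_ids=np.arange(1, len(positions) + 1),
        starts=starts, ends=ends, positions=positions,
        raw_counts=counts,
        distances=np.maximum(0, starts - bait_end),
    )


class TestCallerParams:
    @pytest.mark.parametrize("kwargs", [
        {"w": 2}, {"s": 0.0}, {"s": 1.5}, {"c": 0}, {"b": -1},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CallerParams(**kwargs)

    def test_defaults_match_shipped_configuration(self):
        p = CallerParams()
        assert (p.w, p.s, p.c, p.b) == (20, 0.05, 1_500_000, 30_000)


class TestBuildVirtual4C:
    def test_cis_window_excludes_distant_fragments(self, tiling_map):
        # other ends at 0.5 Mb and 2.0 Mb from the bait; c = 1.5 Mb
        rows = []
        for oe_start, oe_id in [(500_000, 600), (2_000_000, 700)]:
            rows.append({
                "ID_Bait": 1, "chr_Bait": "chr1", "start_Bait": 0,
                "end_Bait": 1000, "Bait_name": "bait_1",
                "ID_OE": oe_id, "chr_OE": "chr1", "start_OE": oe_start,
                "end_OE": oe_start + 1000, "N": 4,
            })
        table = InteractionTable(pd.DataFrame(rows))
        prof = build_virtual_4c(table, 1, {1}, CallerParams())
        assert list(prof.oe_ids) == [600]

    def test_bait_to_bait_excluded(self):
        t = make_table([(5, 2, 3), (5, 12, 2)])
        prof = build_virtual_4c(t, 5, {5, 12}, CallerParams())
        assert list(prof.oe_ids) == [2]

    def test_matches_brute_force_filter_and_sort(self):
        rng = np.random.default_rng(21)
        t = make_table([(5, o, int(rng.integers(1, 9)))
                        for o in range(20) if o != 5])
        baits = {5, 11}
        params = CallerParams(c=6000)
        prof = build_virtual_4c(t, 5, baits, params)
        expect = []
        for r in t.df.itertuples():
            gap = max(0, r.start_OE - r.end_Bait, r.start_Bait - r.end_OE)
            if r.chr_OE == r.chr_Bait and r.ID_OE not in baits and gap <= 6000:
                expect.append((0.5 * (r.start_OE + r.end_OE), r.ID_OE))
        expect.sort()
        assert list(prof.oe_ids) == [e[1] for e in expect]
        assert np.all(np.diff(prof.positions) > 0)


class TestLoessSmooth:
    def test_constant_counts_reproduced(self):
        x = np.arange(100, dtype=float) * 500
        sm = loess_smooth(x, np.full(100, 7.0), 0.1)
        assert np.max(np.abs(sm - 7.0)) < 1e-9

    def test_linear_counts_reproduced(self):
        x = np.arange(200, dtype=float) * 500
        y = 2.0 + 0.003 * x
        sm = loess_smooth(x, y, 0.1)
        assert np.max(np.abs(sm - y) / y) < 1e-6

    def test_matches_independent_lowess_implementation(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 1e6, 200))
        y = rng.poisson(5, size=200).astype(float) + 1
        sm = loess_smooth(x, y, 0.05)
        ref = manual_lowess(x, y, 0.05)
        assert np.max(np.abs(sm - ref) / np.abs(ref)) < 1e-6

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            loess_smooth([3.0, 1.0, 2.0, 4.0], [1.0, 1, 1, 1], 0.5)


class TestFindLocalMaxima:
    def test_unique_apex(self):
        assert list(find_local_maxima(np.array([1, 2, 5, 2, 1.0]), 5)) == [2]

    @pytest.mark.parametrize("w", [3, 10, 20])
    def test_plateau_returns_all_tied_indices(self, w):
        assert list(find_local_maxima(np.full(30, 2.5), w)) == list(range(30))

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(13)
        sm = np.round(rng.uniform(0, 10, 500), 1)  # rounded to force ties
        got = list(find_local_maxima(sm, 20))
        assert got == brute_force_windowed_maxima(sm, 20)


class TestDistanceBinGeomeans:
    def test_exact_small_cases(self):
        prof = profile_from_arrays([1000, 2000, 3000], [1, 4, 16], frag=500)
        table = distance_bin_geomeans(prof, 30_000)
        assert table.geomeans[0] == pytest.approx(4.0, abs=1e-12)
        single = profile_from_arrays([1000], [7], frag=500)
        assert distance_bin_geomeans(single, 30_000).geomeans[0] == pytest.approx(7.0)

    def test_matches_log_mean_oracle(self):
        rng = np.random.default_rng(31)
        pos = np.sort(rng.choice(np.arange(1, 400) * 997, 200, replace=False)).astype(float)
        counts = rng.integers(1, 40, size=200).astype(float)
        prof = profile_from_arrays(pos, counts, frag=400)
        table = distance_bin_geomeans(prof, 30_000)
        bins = (prof.distances // 30_000).astype(int)
        for k in np.unique(bins):
            expect = float(np.exp(np.mean(np.log(counts[bins == k]))))
            assert table.geomeans[int(k)] == pytest.approx(expect, rel=1e-12)


class TestCallBait:
    def test_constant_profile_yields_no_calls(self):
        """All indices are tied maxima; the strict inequality removes them all."""
        pos = np.arange(200, dtype=float) * 1000 + 500
        prof = profile_from_arrays(pos, np.full(200, 4.0))
        for w, s, b in [(5, 0.2, 10_000), (20, 0.05, 30_000), (50, 0.5, 5_000)]:
            calls = call_bait(prof, CallerParams(w=w, s=s, b=b))
            assert len(calls) == 0

    def test_flat_background_single_planted_spike(self):
        """100-fragment flat profile of 2 reads with one fragment of 40 reads."""
        counts = np.full(100, 2.0)
        counts[60] = 40.0
        pos = np.arange(100, dtype=float) * 1000 + 500
        prof = profile_from_arrays(pos, counts)
        calls = call_bait(prof, CallerParams(w=20, s=0.05, b=30_000))
        assert list(calls["ID_OE"]) == [prof.oe_ids[60]]

    def test_power_law_profile_with_three_planted_peaks(self):
        """Strong peaks over a power-law decay are recovered within +-2 fragments.

        The bait-adjacent apex of the decay is itself always a windowed
        maximum (the expected background summit) and is ignored here.
        """
        rng = np.random.default_rng(2)
        n = 600
        pos = np.arange(n, dtype=float) * 1000 + 500
        dist = pos - 500
        mu = 2.5e5 / (dist + 5000)
        counts = np.maximum(1, np.round(mu + rng.normal(0, 0.05 * mu)))
        peaks = [120, 250, 400]
        sm_bg = loess_smooth(pos, counts, 0.05)
        for p in peaks:
            counts[p - 2:p + 3] = np.maximum(counts[p - 2:p + 3], 5.0 * sm_bg[p])
        prof = profile_from_arrays(pos, counts)
        calls = call_bait(prof, CallerParams(w=50, s=0.05, b=30_000))
        idx = [int(np.flatnonzero(prof.oe_ids == o)[0]) for o in calls["ID_OE"]]
        idx = [i for i in idx if prof.distances[i] >= 30_000]  # drop decay apex
        for p in peaks:
            assert any(abs(i - p) <= 2 for i in idx), f"peak at {p} not recovered"
        assert all(any(abs(i - p) <= 2 for p in peaks) for i in idx)

    def test_every_call_satisfies_retention_conditions(self):
        rng = np.random.default_rng(17)
        pos = np.sort(rng.choice(np.arange(1, 2990) * 497, 800, replace=False)).astype(float)
        counts = rng.integers(1, 30, size=800).astype(float)
        prof = profile_from_arrays(pos, counts, frag=400)
        params = CallerParams(w=20)
        calls = call_bait(prof, params)
        assert len(calls) > 0
        assert (calls["smoothed_value"] > calls["bin_geomean"]).all()
        assert (calls["distance_to_bait"] <= params.c).all()

    def test_collapse_plateaus_keeps_one_per_run(self):
        pos = np.arange(100, dtype=float) * 1000 + 500
        prof = profile_from_arrays(pos, np.full(100, 2.0))
        # plateau of maxima; disable the geomean filter effect by spiking bin
        prof.raw_counts[50] = 3.0
        full = call_bait(prof, CallerParams(w=10, s=0.3))
        collapsed = call_bait(prof, CallerParams(w=10, s=0.3, collapse_plateaus=True))
        assert len(collapsed) <= len(full)

    def test_count_scaling_invariance(self):
        """Scaling all raw counts by k > 0 leaves the called set unchanged."""
        rng = np.random.default_rng(23)
        pos = np.sort(rng.choice(np.arange(1, 3000) * 997, 500, replace=False)).astype(float)
        counts = rng.integers(1, 25, size=500).astype(float)
        params = CallerParams(w=20)
        base = call_bait(profile_from_arrays(pos, counts, frag=400), params)
        scaled = call_bait(profile_from_arrays(pos, 7.5 * counts, frag=400), params)
        assert list(base["ID_OE"]) == list(scaled["ID_OE"])

    def test_window_monotonicity_of_maxima(self):
        """Maxima for a wider window are a subset of maxima for a narrower one."""
        rng = np.random.default_rng(29)
        sm = rng.uniform(0, 10, 400)
        for w1, w2 in [(3, 10), (10, 20), (20, 50)]:
            m1 = set(find_local_maxima(sm, w1).tolist())
            m2 = set(find_local_maxima(sm, w2).tolist())
            assert m2 <= m1


class TestCallDataset:
    def test_single_bait_equals_call_bait(self):
        rng = np.random.default_rng(41)
        rows = [(5, o, int(rng.integers(1, 20))) for o in range(20) if o != 5]
        t = make_table(rows)
        params = CallerParams(w=3, s=0.5, c=1_500_000)
        via_dataset = call_dataset(t, {5}, params)
        prof = build_virtual_4c(t, 5, {5}, params)
        direct = call_bait(prof, params)
        assert list(via_dataset.df["ID_OE"]) == list(direct["ID_OE"])

    def test_per_bait_independence(self):
        rng = np.random.default_rng(43)
        rows_a = [(5, o, int(rng.integers(1, 20))) for o in range(20) if o not in (5, 12)]
        rows_b = [(12, o, int(rng.integers(1, 20))) for o in range(20) if o not in (5, 12)]
        params = CallerParams(w=3, s=0.5)
        both = call_dataset(make_table(rows_a + rows_b), {5, 12}, params)
        only_a = call_dataset(make_table(rows_a), {5, 12}, params)
        only_b = call_dataset(make_table(rows_b), {5, 12}, params)
        merged = set(zip(both.df["ID_Bait"], both.df["ID_OE"]))
        separate = set(zip(only_a.df["ID_Bait"], only_a.df["ID_OE"])) | set(
            zip(only_b.df["ID_Bait"], only_b.df["ID_OE"]))
        assert merged == separate

    def test_row_order_invariance(self):
        rng = np.random.default_rng(47)
        rows = [(b, o, int(rng.integers(1, 20)))
                for b in (5, 12) for o in range(20) if o not in (5, 12)]
        t = make_table(rows)
        params = CallerParams(w=3, s=0.5)
        shuffled = InteractionTable(
            t.df.sample(frac=1, random_state=1).reset_index(drop=True)
        )
        a = call_dataset(t, {5, 12}, params)
        b = call_dataset(shuffled, {5, 12}, params)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_tiny_bait_skipped_with_warning(self, caplog):
        t = make_table([(5, 2, 3), (5, 3, 1)])
        out = call_dataset(t, {5}, CallerParams(w=3))
        assert len(out) == 0
        assert "too few" in caplog.text
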