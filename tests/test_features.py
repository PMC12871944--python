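"""Feature-engineering oracles: GPS math, sensor blocks, aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

import phenorisk as pr
from phenorisk.features import (
    SENTINEL,
    app_usage_block,
    battery_block,
    fit_apply_normalizer,
    location_feature_block,
    mindcraft_block,
    reading_stats_block,
    steps_block,
)
from phenorisk.registry import CATEGORY_COUNTS, feature_registry

EARTH_R = 6_371_000.0


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def test_registry_totals_and_category_counts():
    reg = feature_registry()
    assert len(reg) == 92
    by_cat = {}
    for s in reg:
        by_cat[s.category] = by_cat.get(s.category, 0) + 1
    assert by_cat == CATEGORY_COUNTS
    names = [s.name for s in reg]
    assert len(set(names)) == 92


# ---------------------------------------------------------------------------
# haversine
# ---------------------------------------------------------------------------

def _sloc_distance(lat1, lon1, lat2, lon2):
    """Independent oracle: spherical law of cosines."""
    p1, l1, p2, l2 = map(math.radians, (lat1, lon1, lat2, lon2))
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(l2 - l1)
    return EARTH_R * math.acos(min(1.0, max(-1.0, c)))


def test_haversine_identity_and_antipode():
    assert pr.haversine_m(51.5, -0.1, 51.5, -0.1) == 0.0
    assert pr.haversine_m(0, 0, 0, 180) == pytest.approx(math.pi * EARTH_R, rel=1e-12)


def test_haversine_matches_law_of_cosines_oracle(rng):
    for _ in range(50):
        lat1, lat2 = rng.uniform(-80, 80, 2)
        lon1, lon2 = rng.uniform(-180, 180, 2)
        assert pr.haversine_m(lat1, lon1, lat2, lon2) == pytest.approx(
            _sloc_distance(lat1, lon1, lat2, lon2), abs=1.0)
    assert pr.haversine_m(51.5, -0.1, 51.5, 0.0) == pytest.approx(
        _sloc_distance(51.5, -0.1, 51.5, 0.0), abs=1.0)


def test_haversine_rejects_bad_coords():
    with pytest.raises(ValueError):
        pr.haversine_m(np.nan, 0, 0, 0)
    with pytest.raises(ValueError):
        pr.haversine_m(95, 0, 0, 0)


# ---------------------------------------------------------------------------
# jump filter
# ---------------------------------------------------------------------------

def test_jump_filter_stationary_unchanged():
    h = np.array([1.0, 2.0, 3.0])
    la = np.full(3, 51.5)
    lo = np.full(3, -0.1)
    fh, fla, flo = pr.filter_gps_jumps(h, la, lo)
    assert np.array_equal(fh, h) and np.array_equal(fla, la)


def test_jump_filter_removes_teleport():
    # middle fix 500 km away within 5 minutes: implied speed ~6000 km/h
    h = np.array([10.0, 10.083, 10.167])
    la = np.array([51.5, 47.0, 51.5])
    lo = np.array([-0.1, -0.1, -0.1])
    fh, fla, flo = pr.filter_gps_jumps(h, la, lo)
    assert len(fh) == 2 and np.all(fla == 51.5)


def _brute_force_filter(h, la, lo, vmax):
    keep = [0]
    for i in range(1, len(h)):
        j = keep[-1]
        d = pr.haversine_m(la[j], lo[j], la[i], lo[i]) / 1000.0
        dt = h[i] - h[j]
        if dt <= 0:
            if d <= 1e-9:
                keep.append(i)
            continue
        if d / dt <= vmax:
            keep.append(i)
    return keep


def test_jump_filter_matches_sequential_oracle(rng):
    for _ in range(20):
        n = 30
        h = np.sort(rng.uniform(0, 24, n))
        la = 51.5 + rng.normal(0, 0.05, n)
        lo = -0.1 + rng.normal(0, 0.05, n)
        # inject teleports
        la[rng.integers(1, n, 3)] += rng.choice([-5, 5], 3)
        fh, _, _ = pr.filter_gps_jumps(h, la, lo, 200)
        keep = _brute_force_filter(h, la, lo, 200)
        assert np.array_equal(fh, h[keep])


# ---------------------------------------------------------------------------
# home inference
# ---------------------------------------------------------------------------

def test_infer_home_night_modal_cell():
    hours = np.array([23.0, 23.5, 1.0, 12.0])
    lats = np.array([51.5, 51.5, 51.5, 51.9])
    lons = np.array([-0.1, -0.1, -0.1, -0.5])
    assert pr.infer_home(hours, lats, lons) == (51.5, -0.1)


def test_infer_home_majority_and_tie_rules():
    # 3 fixes in cell A, 2 in cell B -> A
    hours = np.full(5, 23.0)
    lats = np.array([51.5, 51.5, 51.5, 51.6, 51.6])
    lons = np.full(5, -0.1)
    assert pr.infer_home(hours, lats, lons) == (51.5, -0.1)
    # exact tie -> earliest-observed cell
    hours = np.full(4, 23.0)
    lats = np.array([51.6, 51.5, 51.6, 51.5])
    assert pr.infer_home(hours, lats, lons[:4]) == (51.6, -0.1)


def test_infer_home_daytime_fallback_and_empty():
    hours = np.array([12.0, 13.0])
    assert pr.infer_home(hours, np.array([51.5, 51.5]), np.array([-0.1, -0.1])) == (51.5, -0.1)
    assert pr.infer_home(np.array([]), np.array([]), np.array([])) is None


# ---------------------------------------------------------------------------
# radius of gyration & entropy
# ---------------------------------------------------------------------------

def test_radius_of_gyration_degenerate_and_symmetric():
    assert pr.radius_of_gyration(np.full(5, 51.5), np.full(5, -0.1)) == 0.0
    # two fixes on one meridian separated by d: rog ~ d/2
    d = pr.haversine_m(51.5, -0.1, 51.51, -0.1)
    rog = pr.radius_of_gyration(np.array([51.5, 51.51]), np.array([-0.1, -0.1]))
    assert rog == pytest.approx(d / 2, rel=1e-3)


def test_radius_of_gyration_matches_formula_oracle(rng):
    lats = 51.5 + rng.normal(0, 0.01, 20)
    lons = -0.1 + rng.normal(0, 0.01, 20)
    clat, clon = lats.mean(), lons.mean()
    expected = math.sqrt(np.mean([
        pr.haversine_m(a, b, clat, clon) ** 2 for a, b in zip(lats, lons)
    ]))
    assert pr.radius_of_gyration(lats, lons) == pytest.approx(expected, rel=1e-6)


def test_location_entropy_closed_forms():
    assert pr.location_entropy(np.full(5, 51.5), np.full(5, -0.1)) == 0.0
    lats = np.array([51.501, 51.502, 51.503, 51.504])
    assert pr.location_entropy(lats, np.full(4, -0.1)) == pytest.approx(math.log(4), rel=1e-12)
    # counts (5, 3, 2)
    lats = np.concatenate([np.full(5, 51.501), np.full(3, 51.502), np.full(2, 51.503)])
    p = np.array([0.5, 0.3, 0.2])
    assert pr.location_entropy(lats, np.full(10, -0.1)) == pytest.approx(
        float(-(p * np.log(p)).sum()), rel=1e-12)


# ---------------------------------------------------------------------------
# location block
# ---------------------------------------------------------------------------

def test_location_block_single_home_fix():
    out = location_feature_block(np.array([12.0]), np.array([51.5]), np.array([-0.1]),
                                 home=(51.5, -0.1))
    assert out["loc_total_distance"] == 0.0
    assert out["loc_time_at_home"] == 1.0
    assert out["loc_entropy"] == 0.0
    assert out["loc_max_dist_home"] == 0.0
    assert out["loc_night_movement"] == 0.0
    assert out["loc_fix_count"] == 1.0


def test_location_block_daytime_pair():
    la = np.array([51.5, 51.5])
    lo = np.array([-0.1, -0.08556])  # ~1000 m apart at this latitude
    d = pr.haversine_m(la[0], lo[0], la[1], lo[1])
    out = location_feature_block(np.array([10.0, 11.0]), la, lo, home=(51.5, -0.1))
    assert out["loc_total_distance"] == pytest.approx(d)
    assert out["loc_night_movement"] == 0.0


def test_location_block_matches_per_formula_oracles(rng):
    n = 50
    hours = np.sort(rng.uniform(0, 24, n))
    lats = 51.5 + rng.normal(0, 0.02, n)
    lons = -0.1 + rng.normal(0, 0.02, n)
    home = pr.infer_home(hours, lats, lons)
    out = location_feature_block(hours, lats, lons, home)
    assert out["loc_mean_lat"] == pytest.approx(lats.mean())
    assert out["loc_sd_lon"] == pytest.approx(lons.std())
    assert out["loc_fix_count"] == n
    seg = [pr.haversine_m(lats[i], lons[i], lats[i + 1], lons[i + 1]) for i in range(n - 1)]
    assert out["loc_total_distance"] == pytest.approx(sum(seg), rel=1e-9)
    night = (hours >= 22) | (hours < 6)
    nm = sum(s for i, s in enumerate(seg) if night[i] and night[i + 1])
    assert out["loc_night_movement"] == pytest.approx(nm, rel=1e-9)
    assert out["loc_radius_gyration"] == pytest.approx(pr.radius_of_gyration(lats, lons))
    assert out["loc_entropy"] == pytest.approx(pr.location_entropy(lats, lons))
    dh = [pr.haversine_m(a, b, home[0], home[1]) for a, b in zip(lats, lons)]
    assert out["loc_max_dist_home"] == pytest.approx(max(dh))
    assert out["loc_median_dist_home"] == pytest.approx(float(np.median(dh)))
    dc = [pr.haversine_m(a, b, lats.mean(), lons.mean()) for a, b in zip(lats, lons)]
    assert out["loc_max_dist_centroid"] == pytest.approx(max(dc))


def test_location_block_empty_is_sentinel():
    out = location_feature_block(np.array([]), np.array([]), np.array([]), None)
    assert all(v == SENTINEL for v in out.values())
    assert len(out) == 15


# ---------------------------------------------------------------------------
# reading stats / app / battery / steps / in-app blocks
# ---------------------------------------------------------------------------

def test_reading_stats_constant_series():
    hours = np.array([10.0, 11.0, 12.0])
    out = reading_stats_block(hours, np.full(3, 7.0), "light")
    assert out["light_total_day"] == 21.0
    assert out["light_mean_day"] == out["light_median_day"] == 7.0
    assert out["light_sd_day"] == 0.0
    # no night samples -> night block all sentinel
    assert out["light_total_night"] == SENTINEL
    assert out["light_sd_night"] == SENTINEL


def test_reading_stats_matches_summary_oracle(rng):
    hours = rng.uniform(0, 24, 40)
    vals = rng.gamma(2.0, 10.0, 40)
    out = reading_stats_block(hours, vals, "noise", with_max=True)
    night = (hours >= 22) | (hours < 6)
    assert out["noise_total_day"] == pytest.approx(vals.sum())
    assert out["noise_mean_day"] == pytest.approx(vals.mean())
    assert out["noise_median_day"] == pytest.approx(np.median(vals))
    assert out["noise_max_day"] == pytest.approx(vals.max())
    assert out["noise_sd_day"] == pytest.approx(vals.std())
    if night.any():
        assert out["noise_mean_night"] == pytest.approx(vals[night].mean())


def test_app_block_single_entertainment_session():
    out = app_usage_block(np.array([14.0]), np.array(["ent_0"]),
                          np.array(["entertainment"]), np.array([60.0]))
    assert out["app_count_day"] == 1.0
    assert out["app_unique_day"] == 1.0
    assert out["app_total_time_day"] == 60.0
    assert out["app_cat_entertainment_pct"] == 100.0
    assert out["app_cat_gaming_time"] == 0.0
    assert out["app_cat_gaming_pct"] == 0.0
    assert out["app_count_night"] == 0.0  # observed zero, not unavailable
    assert out["app_mean_time_night"] == SENTINEL


def test_app_block_mixed_day_matches_hand_oracle():
    hours = np.array([9.0, 23.0, 13.0, 23.5])
    ids = np.array(["a", "b", "a", "c"])
    cats = np.array(["social_media", "gaming", "social_media", "communication"])
    dur = np.array([100.0, 50.0, 150.0, 200.0])
    out = app_usage_block(hours, ids, cats, dur)
    assert out["app_count_day"] == 4.0
    assert out["app_unique_day"] == 3.0
    assert out["app_count_night"] == 2.0
    assert out["app_total_time_night"] == 250.0
    assert out["app_cat_social_media_time"] == 250.0
    assert out["app_cat_social_media_pct"] == pytest.approx(100 * 250 / 500)
    assert out["app_cat_gaming_pct"] == pytest.approx(10.0)
    pct = [out[f"app_cat_{c}_pct"] for c in
           ("camera", "communication", "entertainment", "gaming", "physical_health",
            "mental_health", "mindcraft", "news", "productivity", "social_media")]
    assert sum(pct) == pytest.approx(100.0, abs=1e-6)
    assert out["app_first_hour"] == 9.0
    assert out["app_last_hour"] == 23.0
    assert out["app_unique_cats_day"] == 3.0


def test_battery_monotone_and_sawtooth():
    hours = np.arange(0, 24, 0.25)
    levels = np.linspace(100, 52, len(hours))
    out = battery_block(hours, levels)
    assert out["battery_charge_count"] == 0.0
    assert out["battery_drain_per_hour"] == pytest.approx(2.0, rel=1e-2)
    assert out["battery_level_min"] == pytest.approx(52.0)
    # sawtooth: two separate charging episodes
    levels2 = np.concatenate([
        np.linspace(80, 30, 30), np.linspace(35, 90, 12),
        np.linspace(88, 40, 42), np.linspace(45, 95, 12),
    ])
    out2 = battery_block(hours, levels2)
    assert out2["battery_charge_count"] == 2.0


def test_battery_matches_event_scan_oracle(rng):
    hours = np.arange(0, 24, 0.25)
    levels = np.clip(80 + np.cumsum(rng.normal(-0.4, 1.2, len(hours))), 0, 100)
    out = battery_block(hours, levels)
    diffs = np.diff(levels)
    charges = sum(1 for i in range(len(diffs))
                  if diffs[i] > 0 and (i == 0 or diffs[i - 1] <= 0))
    assert out["battery_charge_count"] == charges
    assert out["battery_hours_below_20"] == pytest.approx((levels < 20).sum() * 0.25)
    night = (hours >= 22) | (hours < 6)
    usage = sum(1 for i in range(1, len(levels)) if night[i] and diffs[i - 1] < 0)
    assert out["battery_night_usage_count"] == usage


@pytest.mark.parametrize("steps,expected", [
    (7500, (1.0, 0.0, 0.0)),   # strict >
    (7501, (1.0, 1.0, 0.0)),
    (12000, (1.0, 1.0, 1.0)),
    (100, (0.0, 0.0, 0.0)),
])
def test_steps_indicators_strict(steps, expected):
    out = steps_block(steps)
    assert (out["steps_gt_5000"], out["steps_gt_7500"], out["steps_gt_10000"]) == expected


def test_mindcraft_first_last_night():
    out = mindcraft_block(np.array([7.0, 23.5]))
    assert out["mindcraft_first_hour"] == 7.0
    assert out["mindcraft_last_hour"] == 23.0
    assert out["mindcraft_night_count"] == 1.0


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def test_assemble_platform_gating_and_zero_sensor(small_cohort, small_matrix):
    df = small_matrix.df
    profiles = small_cohort.profiles.set_index("user_id")
    android_only = [s.name for s in small_matrix.registry
                    if s.category in ("ambient_light", "app_usage", "noise")]
    ios_only = [s.name for s in small_matrix.registry if s.category == "screen_brightness"]
    for uid, prof in profiles.iterrows():
        rows = df[df.user_id == uid]
        if prof.platform == "ios":
            assert (rows[android_only].to_numpy() == SENTINEL).all()
        else:
            assert (rows[ios_only].to_numpy() == SENTINEL).all()
        if not prof.enabled_sensors:
            assert (rows[small_matrix.passive_columns].to_numpy() == SENTINEL).all()


def test_assemble_duplicate_user_day_rejected(small_cohort):
    import copy

    bad = copy.copy(small_cohort)
    bad.active = pd.concat([small_cohort.active, small_cohort.active.iloc[:1]],
                           ignore_index=True)
    with pytest.raises(ValueError):
        pr.assemble_daily_features(bad)


def test_assemble_full_sensor_user_matches_block_oracles():
    rates = {k: 1.0 for k in pr.CohortConfig().sensor_optin_rates}
    cfg = pr.CohortConfig(n_users=3, n_days=4, seed=9, sensor_optin_rates=rates,
                          zero_sensor_fraction=0.0, active_retention_final=1.0)
    cohort = pr.generate_cohort(cfg)
    matrix = pr.assemble_daily_features(cohort)
    uid = cohort.profiles.user_id.iloc[0]
    day = 2
    row = matrix.df[(matrix.df.user_id == uid) & (matrix.df.day == day)].iloc[0]
    bat = cohort.sensors["battery"]
    bat = bat[(bat.user_id == uid) & (bat.day == day)]
    expect = battery_block(bat["hour"].to_numpy(), bat["level"].to_numpy())
    for k, v in expect.items():
        assert row[k] == pytest.approx(v)
    steps = cohort.sensors["step_count"]
    sval = steps[(steps.user_id == uid) & (steps.day == day)]["steps"].iloc[0]
    assert row["steps_count"] == float(sval)


# ---------------------------------------------------------------------------
# cumulative median
# ---------------------------------------------------------------------------

def _prefix_median_oracle(series):
    out = []
    obs = []
    for v in series:
        if v != SENTINEL:
            obs.append(v)
        out.append(float(np.median(sorted(obs))) if obs else SENTINEL)
    return out


def _tiny_matrix(values_by_user: dict) -> pr.FeatureMatrix:
    reg = feature_registry()
    rows = []
    for uid, series in values_by_user.items():
        for day, v in enumerate(series, start=1):
            row = {"user_id": uid, "day": day, "active_mood": v}
            row.update({s.name: SENTINEL for s in reg})
            rows.append(row)
    return pr.FeatureMatrix(pd.DataFrame(rows), reg, ["mood"])


def test_cumulative_median_constant_and_outlier():
    m = _tiny_matrix({"a": [5.0] * 4, "b": [5000.0, 5200.0, 90000.0]})
    agg = pr.cumulative_median_aggregate(m)
    a = agg.df[agg.df.user_id == "a"]["active_mood"].tolist()
    assert a == [5.0] * 4
    b = agg.df[agg.df.user_id == "b"]["active_mood"].tolist()
    assert b[2] == 5200.0  # median of the three-day prefix


def test_cumulative_median_matches_prefix_oracle(rng):
    series = list(rng.normal(size=10))
    series[3] = SENTINEL
    series[7] = SENTINEL
    m = _tiny_matrix({"x": series})
    agg = pr.cumulative_median_aggregate(m)
    got = agg.df["active_mood"].tolist()
    assert got == pytest.approx(_prefix_median_oracle(series))


def test_cumulative_median_outlier_robustness():
    """With >= 3 equal prior values, a single-day spike leaves it unchanged."""
    m = _tiny_matrix({"x": [4.0, 4.0, 4.0, 400.0]})
    agg = pr.cumulative_median_aggregate(m)
    assert agg.df["active_mood"].tolist() == [4.0, 4.0, 4.0, 4.0]


def test_cumulative_median_bounded_by_prefix_extremes(rng):
    series = list(rng.normal(size=12))
    m = _tiny_matrix({"x": series})
    agg = pr.cumulative_median_aggregate(m)
    got = agg.df["active_mood"].to_numpy()
    for t in range(12):
        assert min(series[:t + 1]) <= got[t] <= max(series[:t + 1])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalizer_population_sd_and_sentinel():
    m = _tiny_matrix({"a": [2.0, 4.0, 6.0], "b": [SENTINEL, 3.0, 5.0]})
    train = m.df.user_id.to_numpy() == "a"
    normed, state = fit_apply_normalizer(m, train)
    a_vals = normed.df[normed.df.user_id == "a"]["active_mood"].to_numpy()
    assert a_vals == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)
    b_vals = normed.df[normed.df.user_id == "b"]["active_mood"].to_numpy()
    assert b_vals[0] == SENTINEL  # sentinel survives the transform
    # test rows use training statistics only
    mu, sd = 4.0, np.std([2.0, 4.0, 6.0])
    assert b_vals[1] == pytest.approx((3.0 - mu) / sd)


def test_normalizer_binary_columns_untouched(small_matrix):
    m = small_matrix.copy()
    train = np.ones(len(m.df), dtype=bool)
    before = m.df["steps_gt_5000"].to_numpy().copy()
    normed, _ = fit_apply_normalizer(m, train)
    assert np.array_equal(normed.df["steps_gt_5000"].to_numpy(), before)


def test_normalizer_no_training_leakage(small_matrix):
    """Transformed training columns re-center to ~0; test stats unused."""
    m = small_matrix.copy()
    n = len(m.df)
    train = np.zeros(n, dtype=bool)
    train[: n // 2] = True
    normed, state = fit_apply_normalizer(m, train)
    vals = normed.df.loc[train, "active_mood"].to_numpy()
    obs = vals[vals != SENTINEL]
    if len(obs):
        assert abs(obs.mean()) < 1e-9


def test_normalizer_requires_two_training_rows(small_matrix):
    with pytest.raises(ValueError):
        fit_apply_normalizer(small_matrix, np.zeros(len(small_matrix.df), dtype=bool))
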