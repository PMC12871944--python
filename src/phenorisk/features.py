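"""Per-user-day feature engineering from raw sensor streams.

Raw event streams (GPS fixes, 15-minute sensor grids, app events, daily
step counts, in-app sessions) are turned into one numeric row per user-day:
the daily self-report items plus the 92 passive features of the registry.
Statistics are computed over two windows — the full 24-hour day and the
night window [22:00, 06:00) in local time — and a feature whose sensor is
unavailable (not enabled, platform-gated, or simply no data that day) is
coded with the sentinel value -1.

Daily rows are then smoothed per user with the *cumulative median* (the
median of all observed values up to each day), and z-scored with training
statistics only; sentinels are excluded from both steps and reinserted
afterwards so -1 always means "unavailable".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import (
    APP_CATEGORIES,
    FeatureSpec,
    available_categories,
    feature_registry,
)

logger = logging.getLogger(__name__)

SENTINEL = -1.0
EARTH_RADIUS_M = 6_371_000.0
NIGHT_START = 22.0  # inclusive
NIGHT_END = 6.0  # exclusive
GRID_DECIMALS = 3  # lat/lon rounding -> ~111 m cells
DEFAULT_MAX_SPEED_KMH = 200.0


def is_night(hours: np.ndarray) -> np.ndarray:
    """Boolean mask for the half-open night window [22:00, 06:00)."""
    hours = np.asarray(hours, dtype=float) % 24.0
    return (hours >= NIGHT_START) | (hours < NIGHT_END)


# ---------------------------------------------------------------------------
# GPS primitives
# ---------------------------------------------------------------------------

def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in meters between coordinate pairs in degrees."""
    arrs = [np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2)]
    if any(not np.all(np.isfinite(a)) for a in arrs):
        raise ValueError("non-finite coordinate passed to haversine_m")
    if np.any(np.abs(arrs[0]) > 90) or np.any(np.abs(arrs[2]) > 90):
        raise ValueError("latitude outside [-90, 90]")
    p1, l1, p2, l2 = (np.radians(a) for a in arrs)
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def filter_gps_jumps(
    hours: np.ndarray,
    lats: np.ndarray,
    lons: np.ndarray,
    max_speed_kmh: float = DEFAULT_MAX_SPEED_KMH,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop fixes implying impossible speed from the previous retained fix.

    ``hours`` must be chronologically sorted (absolute hours allowed). The
    first fix is always retained. A fix at zero time offset from the last
    retained fix is dropped unless it is at (numerically) zero distance.
    """
    hours = np.asarray(hours, dtype=float)
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    n = len(hours)
    if n == 0:
        return hours, lats, lons
    keep = [0]
    for i in range(1, n):
        j = keep[-1]
        dt_h = hours[i] - hours[j]
        dist_km = haversine_m(lats[j], lons[j], lats[i], lons[i]) / 1000.0
        if dt_h <= 0:
            if dist_km > 1e-9:
                continue
            speed = 0.0
        else:
            speed = dist_km / dt_h
        if speed <= max_speed_kmh:
            keep.append(i)
    idx = np.array(keep, dtype=int)
    return hours[idx], lats[idx], lons[idx]


def grid_cell(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Map coordinates to ~111 m grid cells (3-decimal rounding)."""
    lat_r = np.round(np.asarray(lats, dtype=float), GRID_DECIMALS)
    lon_r = np.round(np.asarray(lons, dtype=float), GRID_DECIMALS)
    return np.stack([lat_r, lon_r], axis=-1)


def infer_home(
    hours: np.ndarray, lats: np.ndarray, lons: np.ndarray
) -> tuple[float, float] | None:
    """Modal night-window grid cell over the whole study; ties break to the
    earliest-observed cell. Falls back to the modal overall cell when the
    user has no night fixes; ``None`` when there are no fixes at all."""
    hours = np.asarray(hours, dtype=float)
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if len(hours) == 0:
        return None
    night = is_night(hours % 24.0)
    sel = night if night.any() else np.ones(len(hours), dtype=bool)
    cells = grid_cell(lats[sel], lons[sel])
    counts: dict[tuple[float, float], int] = {}
    first_seen: dict[tuple[float, float], int] = {}
    for i, cell in enumerate(map(tuple, cells)):
        counts[cell] = counts.get(cell, 0) + 1
        first_seen.setdefault(cell, i)
    best = max(counts, key=lambda c: (counts[c], -first_seen[c]))
    return best


def radius_of_gyration(lats: np.ndarray, lons: np.ndarray) -> float:
    """Root-mean-square haversine distance of fixes to their centroid."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if len(lats) == 0:
        return SENTINEL
    clat, clon = lats.mean(), lons.mean()
    d = haversine_m(lats, lons, clat, clon)
    return float(np.sqrt(np.mean(np.square(d))))


def location_entropy(lats: np.ndarray, lons: np.ndarray) -> float:
    """Shannon entropy (nats) of the fix distribution over grid cells."""
    if len(np.asarray(lats)) == 0:
        return SENTINEL
    cells = grid_cell(lats, lons)
    _, counts = np.unique(cells, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def location_feature_block(
    hours: np.ndarray,
    lats: np.ndarray,
    lons: np.ndarray,
    home: tuple[float, float] | None,
) -> dict[str, float]:
    """The 15 daily location features from one (jump-filtered) track."""
    names = [
        "loc_mean_lat", "loc_mean_lon", "loc_total_distance", "loc_fix_count",
        "loc_max_dist_home", "loc_mean_dist_home", "loc_median_dist_home",
        "loc_night_movement", "loc_radius_gyration", "loc_sd_lat",
        "loc_sd_lon", "loc_entropy", "loc_time_at_home",
        "loc_max_dist_centroid", "loc_entropy_normalized",
    ]
    hours = np.asarray(hours, dtype=float)
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if len(hours) == 0:
        return {k: SENTINEL for k in names}

    out: dict[str, float] = {}
    out["loc_mean_lat"] = float(lats.mean())
    out["loc_mean_lon"] = float(lons.mean())
    seg = haversine_m(lats[:-1], lons[:-1], lats[1:], lons[1:]) if len(lats) > 1 else np.array([])
    out["loc_total_distance"] = float(np.sum(seg))
    out["loc_fix_count"] = float(len(lats))
    night = is_night(hours)
    if len(seg):
        seg_night = night[:-1] & night[1:]
        out["loc_night_movement"] = float(np.sum(np.asarray(seg)[seg_night]))
    else:
        out["loc_night_movement"] = 0.0
    if home is None:
        out["loc_max_dist_home"] = SENTINEL
        out["loc_mean_dist_home"] = SENTINEL
        out["loc_median_dist_home"] = SENTINEL
        out["loc_time_at_home"] = SENTINEL
    else:
        dh = np.atleast_1d(haversine_m(lats, lons, home[0], home[1]))
        out["loc_max_dist_home"] = float(dh.max())
        out["loc_mean_dist_home"] = float(dh.mean())
        out["loc_median_dist_home"] = float(np.median(dh))
        cells = grid_cell(lats, lons)
        at_home = (cells[:, 0] == home[0]) & (cells[:, 1] == home[1])
        out["loc_time_at_home"] = float(at_home.mean())
    out["loc_radius_gyration"] = radius_of_gyration(lats, lons)
    out["loc_sd_lat"] = float(lats.std())
    out["loc_sd_lon"] = float(lons.std())
    ent = location_entropy(lats, lons)
    out["loc_entropy"] = ent
    clat, clon = lats.mean(), lons.mean()
    dc = np.atleast_1d(haversine_m(lats, lons, clat, clon))
    out["loc_max_dist_centroid"] = float(dc.max())
    n_cells = len(np.unique(grid_cell(lats, lons), axis=0))
    out["loc_entropy_normalized"] = float(ent / np.log(n_cells)) if n_cells > 1 else 0.0
    return out


# ---------------------------------------------------------------------------
# Grid-sampled reading sensors (light, noise, brightness)
# ---------------------------------------------------------------------------

def reading_stats_block(
    hours: np.ndarray,
    values: np.ndarray,
    prefix: str,
    with_max: bool = False,
) -> dict[str, float]:
    """Total/mean/median(/max)/SD over the full day and the night window.

    SDs are population SDs (divide by n). A window with no samples emits
    sentinels for all of its statistics.
    """
    stats = ["total", "mean", "median", "max", "sd"] if with_max else ["total", "mean", "median", "sd"]
    hours = np.asarray(hours, dtype=float)
    values = np.asarray(values, dtype=float)
    out: dict[str, float] = {}
    night = is_night(hours)
    for window, sel in (("day", np.ones(len(hours), dtype=bool)), ("night", night)):
        v = values[sel]
        if len(v) == 0:
            for s in stats:
                out[f"{prefix}_{s}_{window}"] = SENTINEL
            continue
        out[f"{prefix}_total_{window}"] = float(v.sum())
        out[f"{prefix}_mean_{window}"] = float(v.mean())
        out[f"{prefix}_median_{window}"] = float(np.median(v))
        if with_max:
            out[f"{prefix}_max_{window}"] = float(v.max())
        out[f"{prefix}_sd_{window}"] = float(v.std())
    return out


# ---------------------------------------------------------------------------
# App usage
# ---------------------------------------------------------------------------

def app_usage_block(
    hours: np.ndarray,
    app_ids: np.ndarray,
    categories: np.ndarray,
    durations_s: np.ndarray,
) -> dict[str, float]:
    """The 36 daily app-usage features from one day's events.

    Count-like night features are observed zeros when the day has events but
    the night window does not; statistic-like night features (mean/median/SD
    of session time) are sentinels in that case.
    """
    hours = np.asarray(hours, dtype=float)
    app_ids = np.asarray(app_ids)
    categories = np.asarray(categories)
    durations_s = np.asarray(durations_s, dtype=float)
    out: dict[str, float] = {}
    all_names = (
        [f"app_{k}_{w}" for w in ("day", "night")
         for k in ("count", "unique", "total_time", "mean_time", "median_time")]
        + [f"app_cat_{c}_time" for c in APP_CATEGORIES]
        + [f"app_cat_{c}_pct" for c in APP_CATEGORIES]
        + ["app_sd_time_day", "app_sd_time_night", "app_first_hour",
           "app_last_hour", "app_unique_cats_day", "app_unique_cats_night"]
    )
    if len(hours) == 0:
        return {k: SENTINEL for k in all_names}

    night = is_night(hours)
    for window, sel in (("day", np.ones(len(hours), dtype=bool)), ("night", night)):
        d = durations_s[sel]
        out[f"app_count_{window}"] = float(sel.sum())
        out[f"app_unique_{window}"] = float(len(np.unique(app_ids[sel])))
        out[f"app_total_time_{window}"] = float(d.sum())
        out[f"app_mean_time_{window}"] = float(d.mean()) if len(d) else SENTINEL
        out[f"app_median_time_{window}"] = float(np.median(d)) if len(d) else SENTINEL
        out[f"app_sd_time_{window}"] = float(d.std()) if len(d) else SENTINEL
        out[f"app_unique_cats_{window}"] = float(len(np.unique(categories[sel])))

    total_time = float(durations_s.sum())
    for cat in APP_CATEGORIES:
        t = float(durations_s[categories == cat].sum())
        out[f"app_cat_{cat}_time"] = t
        out[f"app_cat_{cat}_pct"] = 100.0 * t / total_time if total_time > 0 else 0.0
    out["app_first_hour"] = float(np.floor(hours.min()))
    out["app_last_hour"] = float(np.floor(hours.max()))
    return out


# ---------------------------------------------------------------------------
# Battery
# ---------------------------------------------------------------------------

def battery_block(hours: np.ndarray, levels: np.ndarray) -> dict[str, float]:
    """The 8 daily battery features from 15-minute-grid level readings."""
    names = [
        "battery_level_min", "battery_level_max", "battery_level_mean",
        "battery_level_median", "battery_charge_count",
        "battery_drain_per_hour", "battery_hours_below_20",
        "battery_night_usage_count",
    ]
    hours = np.asarray(hours, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if len(hours) == 0:
        return {k: SENTINEL for k in names}
    order = np.argsort(hours, kind="stable")
    hours, levels = hours[order], levels[order]
    out: dict[str, float] = {
        "battery_level_min": float(levels.min()),
        "battery_level_max": float(levels.max()),
        "battery_level_mean": float(levels.mean()),
        "battery_level_median": float(np.median(levels)),
    }
    diffs = np.diff(levels)
    # a "charge" is an onset of increase: diff > 0 not preceded by diff > 0
    rising = diffs > 0
    onsets = rising & ~np.concatenate([[False], rising[:-1]])
    out["battery_charge_count"] = float(onsets.sum())
    interval = float(np.median(np.diff(hours))) if len(hours) > 1 else 0.25
    hours_observed = interval * len(hours)
    total_drain = float(-diffs[diffs < 0].sum())
    out["battery_drain_per_hour"] = total_drain / hours_observed if hours_observed > 0 else SENTINEL
    out["battery_hours_below_20"] = float((levels < 20).sum()) * interval
    night = is_night(hours)
    dropped = np.concatenate([[False], diffs < 0])
    out["battery_night_usage_count"] = float((night & dropped).sum())
    return out


# ---------------------------------------------------------------------------
# Steps & in-app (Mindcraft) usage
# ---------------------------------------------------------------------------

def steps_block(daily_steps: float | None) -> dict[str, float]:
    """Step count plus strict >5000 / >7500 / >10000 indicators."""
    if daily_steps is None:
        return {k: SENTINEL for k in ("steps_count", "steps_gt_5000", "steps_gt_7500", "steps_gt_10000")}
    s = float(daily_steps)
    if s < 0:
        raise ValueError("negative daily step count")
    return {
        "steps_count": s,
        "steps_gt_5000": float(s > 5000),
        "steps_gt_7500": float(s > 7500),
        "steps_gt_10000": float(s > 10000),
    }


def mindcraft_block(start_hours: np.ndarray) -> dict[str, float]:
    """First/last in-app hour of day (0-23) and count of night sessions."""
    start_hours = np.asarray(start_hours, dtype=float)
    if len(start_hours) == 0:
        return {k: SENTINEL for k in ("mindcraft_first_hour", "mindcraft_last_hour", "mindcraft_night_count")}
    return {
        "mindcraft_first_hour": float(np.floor(start_hours.min())),
        "mindcraft_last_hour": float(np.floor(start_hours.max())),
        "mindcraft_night_count": float(is_night(start_hours).sum()),
    }


# ---------------------------------------------------------------------------
# Feature matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Per user-day feature rows plus the column registry.

    ``df`` holds ``user_id``, ``day``, then one ``active_<item>`` column per
    self-report item and one column per passive FeatureSpec, in registry
    order. Unavailable cells carry the sentinel -1.
    """

    df: pd.DataFrame
    registry: list[FeatureSpec] = field(default_factory=feature_registry)
    active_items: list[str] = field(default_factory=list)

    @property
    def active_columns(self) -> list[str]:
        return [f"active_{item}" for item in self.active_items]

    @property
    def passive_columns(self) -> list[str]:
        return [s.name for s in self.registry]

    @property
    def feature_columns(self) -> list[str]:
        return self.active_columns + self.passive_columns

    def columns_for_modality(self, modality: str) -> list[str]:
        if modality == "active":
            return self.active_columns
        if modality == "passive":
            return self.passive_columns
        if modality == "combined":
            return self.feature_columns
        raise ValueError(f"unknown modality {modality!r}")

    def binary_columns(self) -> list[str]:
        return [s.name for s in self.registry if s.kind == "binary"]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.df.copy(), list(self.registry), list(self.active_items))


def _sensor_groups(df: pd.DataFrame | None) -> dict:
    if df is None or len(df) == 0:
        return {}
    return {k: v for k, v in df.groupby("user_id", sort=False)}


def assemble_daily_features(cohort, registry: list[FeatureSpec] | None = None) -> FeatureMatrix:
    """Build the per-user-day feature matrix for a cohort.

    One row is emitted for every user and every study day. Active items not
    answered that day, and every feature of a sensor the user cannot or did
    not enable (or that produced no data that day), carry the sentinel -1.
    """
    registry = registry or feature_registry()
    passive_names = [s.name for s in registry]
    cfg = cohort.config
    items = list(cohort.active_items)

    active = cohort.active
    if len(active) and active.duplicated(["user_id", "day", "item"]).any():
        raise ValueError("duplicate user-day-item rows in active data")
    active_lookup: dict[tuple, float] = {}
    if len(active):
        active_lookup = {
            (u, d, it): v
            for u, d, it, v in zip(active["user_id"], active["day"], active["item"], active["value"])
        }

    sensors = cohort.sensors
    by_user = {cat: _sensor_groups(sensors.get(cat)) for cat in sensors}

    rows = []
    for prof in cohort.profiles.itertuples(index=False):
        uid = prof.user_id
        enabled = available_categories(prof.platform, set(prof.enabled_sensors.split(";")) if prof.enabled_sensors else set())

        # whole-study GPS preprocessing: jump filter + home inference
        home = None
        loc_by_day: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if "location" in enabled and uid in by_user.get("location", {}):
            g = by_user["location"][uid]
            abs_h = (g["day"].to_numpy(dtype=float) - 1) * 24.0 + g["hour"].to_numpy(dtype=float)
            order = np.argsort(abs_h, kind="stable")
            fh, fla, flo = filter_gps_jumps(
                abs_h[order], g["lat"].to_numpy(dtype=float)[order], g["lon"].to_numpy(dtype=float)[order]
            )
            home = infer_home(fh % 24.0, fla, flo)
            day_idx = (fh // 24.0).astype(int) + 1
            for d in np.unique(day_idx):
                m = day_idx == d
                loc_by_day[int(d)] = (fh[m] % 24.0, fla[m], flo[m])

        def day_slice(cat: str, day: int) -> pd.DataFrame | None:
            g = by_user.get(cat, {}).get(uid)
            if g is None:
                return None
            sl = g[g["day"] == day]
            return sl if len(sl) else None

        for day in range(1, cfg.n_days + 1):
            row: dict[str, float] = {"user_id": uid, "day": day}
            for item in items:
                row[f"active_{item}"] = float(active_lookup.get((uid, day, item), SENTINEL))

            vals: dict[str, float] = {}
            if "location" in enabled and day in loc_by_day:
                h, la, lo = loc_by_day[day]
                vals.update(location_feature_block(h, la, lo, home))
            for cat, prefix, with_max in (
                ("ambient_light", "light", False),
                ("noise", "noise", True),
                ("screen_brightness", "brightness", False),
            ):
                if cat in enabled:
                    sl = day_slice(cat, day)
                    if sl is not None:
                        col = {"light": "lux", "noise": "db", "brightness": "value"}[prefix]
                        vals.update(reading_stats_block(sl["hour"].to_numpy(), sl[col].to_numpy(), prefix, with_max))
            if "app_usage" in enabled:
                sl = day_slice("app_usage", day)
                if sl is not None:
                    vals.update(app_usage_block(
                        sl["hour"].to_numpy(), sl["app_id"].to_numpy(),
                        sl["category"].to_numpy(), sl["duration_s"].to_numpy(),
                    ))
            if "battery" in enabled:
                sl = day_slice("battery", day)
                if sl is not None:
                    vals.update(battery_block(sl["hour"].to_numpy(), sl["level"].to_numpy()))
            if "step_count" in enabled:
                sl = day_slice("step_count", day)
                if sl is not None:
                    vals.update(steps_block(float(sl["steps"].iloc[0])))
            if "mindcraft_usage" in enabled:
                sl = day_slice("mindcraft_usage", day)
                if sl is not None:
                    vals.update(mindcraft_block(sl["start_hour"].to_numpy()))

            for name in passive_names:
                row[name] = vals.get(name, SENTINEL)
            rows.append(row)

    df = pd.DataFrame(rows)
    if df.duplicated(["user_id", "day"]).any():
        raise ValueError("duplicate user-day rows")
    return FeatureMatrix(df=df, registry=registry, active_items=items)


# ---------------------------------------------------------------------------
# Cumulative median & normalization
# ---------------------------------------------------------------------------

def cumulative_median_aggregate(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace each feature value with the median of the user's observed
    values on days 1..t; sentinels are excluded from the median and emitted
    only while no observation exists yet."""
    out = matrix.copy()
    cols = out.feature_columns
    df = out.df.sort_values(["user_id", "day"], kind="stable").reset_index(drop=True)
    vals = df[cols].to_numpy(dtype=float)
    masked = np.where(vals == SENTINEL, np.nan, vals)
    result = np.full_like(masked, np.nan)
    for _, idx in df.groupby("user_id", sort=False).indices.items():
        idx = np.sort(np.asarray(idx))
        block = masked[idx]
        counts = np.cumsum(~np.isnan(block), axis=0)
        for t in range(block.shape[0]):
            prefix = block[: t + 1]
            with np.errstate(all="ignore"):
                med = np.full(prefix.shape[1], np.nan)
                has = counts[t] > 0
                if has.any():
                    import warnings

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        med[has] = np.nanmedian(prefix[:, has], axis=0)
            result[idx[t]] = med
    df[cols] = np.where(np.isnan(result), SENTINEL, result)
    out.df = df
    return out


@dataclass
class NormalizerState:
    """Training-set per-column means/SDs for z-scoring continuous features."""

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray
    binary_columns: list[str]

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "binary_columns": self.binary_columns,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizerState":
        return cls(list(d["columns"]), np.asarray(d["mean"], dtype=float),
                   np.asarray(d["sd"], dtype=float), list(d["binary_columns"]))


def fit_apply_normalizer(
    matrix: FeatureMatrix, train_mask: np.ndarray
) -> tuple[FeatureMatrix, NormalizerState]:
    """Z-score continuous columns with training-row statistics.

    Statistics use population SD over non-sentinel training values only;
    binary indicator columns pass through untouched; sentinels are
    reinserted as -1 after scaling so the unavailable code survives. A
    column with zero training SD is centred with a unit divisor (warning).
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.sum() < 2:
        raise ValueError("need at least 2 training rows to fit the normalizer")
    out = matrix.copy()
    binary = set(out.binary_columns())
    cont = [c for c in out.feature_columns if c not in binary]
    vals = out.df[cont].to_numpy(dtype=float)
    masked = np.where(vals == SENTINEL, np.nan, vals)
    train_vals = masked[train_mask]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean = np.nanmean(train_vals, axis=0)
        sd = np.nanstd(train_vals, axis=0)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    zero_sd = ~np.isfinite(sd) | (sd == 0)
    if zero_sd.any():
        logger.warning("%d feature column(s) have zero training SD; centred with unit divisor",
                       int(zero_sd.sum()))
    sd = np.where(zero_sd, 1.0, sd)
    transformed = (masked - mean) / sd
    out.df[cont] = np.where(np.isnan(transformed), SENTINEL, transformed)
    state = NormalizerState(columns=cont, mean=mean, sd=sd, binary_columns=sorted(binary))
    return out, state


def apply_normalizer(matrix: FeatureMatrix, state: NormalizerState) -> FeatureMatrix:
    """Transform a matrix with previously fitted training statistics."""
    out = matrix.copy()
    vals = out.df[state.columns].to_numpy(dtype=float)
    masked = np.where(vals == SENTINEL, np.nan, vals)
    transformed = (masked - state.mean) / state.sd
    out.df[state.columns] = np.where(np.isnan(transformed), SENTINEL, transformed)
    return out
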