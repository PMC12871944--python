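"""Synthetic smartphone digital-phenotyping cohorts.

Generates 14-day cohorts of adolescent app users with:

* a latent severity structure (one general factor plus four outcome-specific
  factors) driving four clinical scale scores (SDQ, SCI, ED-15, suicidal
  ideation frequency) at configurable high-risk prevalences;
* daily 1-7 self-report items loading on the latent factors plus shared
  within-day state (so e.g. motivation and productivity co-move);
* raw passive sensor streams per user — GPS mobility (two-state
  home/excursion model), daily steps, 15-minute grids for battery, ambient
  light, background noise and screen brightness, app-usage events, and
  in-app sessions — whose distributions shift with latent severity in
  configurable directions (fewer steps, more entertainment app use, more
  nighttime light, quieter/less mobile days at higher severity);
* realistic missingness: geometric dropout of the daily self-reports and
  static per-sensor opt-in with platform gating (ambient light, app usage
  and noise exist on Android only; screen brightness on iOS only).

Everything is deterministic given the config seed. The generator emulates
the published engagement, prevalence and feature-outcome correlation
anchors; it makes no attempt at behavioural realism beyond those.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .registry import SENSOR_CATEGORIES, APP_CATEGORIES, available_categories

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: default daily self-report item registry (name -> loadings)
#: columns: loading on the general severity factor, (specific factor, loading),
#: (shared day factor, coefficient)
ITEM_PARAMS: dict[str, tuple[float, tuple[str, float] | None, tuple[str, float] | None]] = {
    "mood": (-0.50, None, ("affect", 0.8)),
    "sleep_quality": (-0.25, ("ins", -0.20), None),
    "loneliness": (0.50, None, None),
    "confidence": (-0.43, None, None),
    "negative_thinking": (0.58, None, ("rumination", 0.8)),
    "racing_thoughts": (0.50, None, ("rumination", 0.8)),
    "self_care": (-0.36, ("ed", -0.12), None),
    "hopefulness": (-0.47, None, None),
    "motivation": (-0.36, None, ("drive", 1.3)),
    "productivity": (-0.32, None, ("drive", 1.3)),
    "energy": (-0.36, None, ("affect", 0.8)),
    "irritability": (0.40, None, None),
    "sociability": (-0.40, None, None),
    "appetite": (-0.20, ("ed", -0.20), None),
}

DAY_FACTORS = ("affect", "drive", "rumination")
DAY_NOISE_SD = 1.1

#: planted feature-outcome correlation directions used as calibration anchors
#: (feature column in the assembled matrix, score column, expected sign)
ANCHOR_CORRELATIONS = [
    ("active_negative_thinking", "sdq_total", +1),
    ("active_loneliness", "sdq_total", +1),
    ("active_racing_thoughts", "si_frequency", +1),
    ("active_sleep_quality", "sci_total", +1),
    ("active_self_care", "ed15_total", -1),
    ("app_cat_entertainment_time", "si_frequency", +1),
    ("noise_max_day", "sdq_total", -1),
    ("light_median_night", "sci_total", -1),
    ("app_median_time_day", "si_frequency", +1),
]

_SITES = ("school_1", "school_2", "school_3")
_SITE_CENTERS = {"school_1": (51.52, -0.15), "school_2": (51.45, -0.30), "school_3": (51.60, -0.05)}


class ConfigurationError(ValueError):
    pass


class ParseError(ValueError):
    pass


def _default_prevalences() -> dict[str, float]:
    # published high-risk proportions of the 103-user study population
    return {"sdq": 31 / 103, "insomnia": 34 / 103, "si": 38 / 103, "ed": 38 / 103}


def _default_optin_rates() -> dict[str, float]:
    # qualitative ordering of enabled sensors: steps and battery most common,
    # then in-app usage and screen brightness; rates are conditional on the
    # user enabling at least one sensor
    return {
        "step_count": 0.80,
        "battery": 0.75,
        "mindcraft_usage": 0.60,
        "screen_brightness": 0.60,
        "location": 0.55,
        "ambient_light": 0.55,
        "app_usage": 0.55,
        "noise": 0.45,
    }


def _default_effects() -> dict[str, float]:
    return {"active": 1.0, "passive": 1.0}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_users: int = 100
    n_days: int = 14
    prevalences: dict[str, float] = field(default_factory=_default_prevalences)
    effect_sizes: dict[str, float] = field(default_factory=_default_effects)
    ios_fraction: float = 78 / 103
    sensor_optin_rates: dict[str, float] = field(default_factory=_default_optin_rates)
    zero_sensor_fraction: float = 36 / 103
    active_retention_final: float = 14 / 103
    day_noise_scale: float = 1.0
    site_shift: float = 0.0
    steps_median: float = 6000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_users < 2:
            raise ConfigurationError("n_users must be >= 2")
        if self.n_days < 2:
            raise ConfigurationError("n_days must be >= 2 (triplets need two days per user)")
        fracs = {
            "ios_fraction": self.ios_fraction,
            "zero_sensor_fraction": self.zero_sensor_fraction,
            "active_retention_final": self.active_retention_final,
            **{f"prevalence[{k}]": v for k, v in self.prevalences.items()},
            **{f"optin[{k}]": v for k, v in self.sensor_optin_rates.items()},
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} not in [0, 1]")
        if set(self.prevalences) != {"sdq", "insomnia", "si", "ed"}:
            raise ConfigurationError("prevalences must cover sdq/insomnia/si/ed")
        for k, v in self.effect_sizes.items():
            if v < 0:
                raise ConfigurationError(f"effect_sizes[{k}] must be >= 0")
        if self.day_noise_scale < 0 or self.steps_median <= 0:
            raise ConfigurationError("day_noise_scale must be >= 0, steps_median > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)


@dataclass
class Cohort:
    """In-memory cohort: profiles, outcome scores, active responses, raw
    sensor logs, plus the config that produced it."""

    profiles: pd.DataFrame
    outcomes: pd.DataFrame
    active: pd.DataFrame
    sensors: dict[str, pd.DataFrame]
    config: CohortConfig
    active_items: list[str] = field(default_factory=lambda: list(ITEM_PARAMS))


@dataclass
class MobilityDay:
    hours: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    steps: float
    n_excursions: int


# ---------------------------------------------------------------------------
# Latent structure and outcome scores
# ---------------------------------------------------------------------------

GENERAL_FACTOR_WEIGHT = 0.75  # shared severity loading of each outcome trait


def _draw_traits(n: int, rng: np.random.Generator) -> pd.DataFrame:
    g = rng.normal(size=n)
    a = GENERAL_FACTOR_WEIGHT
    b = np.sqrt(1.0 - a ** 2)
    traits = {"trait_g": g}
    for k in ("sdq", "ins", "si", "ed"):
        traits[f"trait_{k}"] = a * g + b * rng.normal(size=n)
    return pd.DataFrame(traits)


def _outcome_scores(traits: pd.DataFrame, prevalences: dict[str, float],
                    rng: np.random.Generator) -> pd.DataFrame:
    """Scale scores as monotone transforms of latent traits plus noise,
    with latent thresholds placed so binarized prevalences approximate the
    configured targets."""
    n = len(traits)
    sd_u = np.sqrt(1.0225)  # trait variance 1 + score-noise variance 0.15^2

    def latent(k: str, p: float) -> np.ndarray:
        u = traits[f"trait_{k}"].to_numpy() + 0.15 * rng.normal(size=n)
        c = norm.ppf(1.0 - p) * sd_u
        return (u - c) / sd_u  # standardized distance above the cut

    z_sdq = latent("sdq", prevalences["sdq"])
    z_ins = latent("ins", prevalences["insomnia"])
    z_si = latent("si", prevalences["si"])
    z_ed = latent("ed", prevalences["ed"])
    return pd.DataFrame({
        "sdq_total": np.clip(np.round(15.5 + 6.0 * z_sdq), 0, 40).astype(int),
        "sci_total": np.clip(np.round(16.5 - 7.0 * z_ins), 0, 32).astype(int),
        "ed15_total": np.clip(2.69 + 1.5 * z_ed, 0.0, 6.0),
        "si_frequency": np.clip(np.round(0.5 + 1.2 * z_si), 0, 4).astype(int),
    })


# ---------------------------------------------------------------------------
# Active data
# ---------------------------------------------------------------------------

def simulate_active_day(
    traits: dict[str, float],
    day: int,
    rng: np.random.Generator,
    active_effect: float = 1.0,
    day_noise_scale: float = 1.0,
    items: list[str] | None = None,
) -> dict[str, int]:
    """One day of 1-7 self-report responses for one user.

    Each item is a clipped, rounded affine function of the user's latent
    traits (scaled by ``active_effect``), shared day factors and noise
    (both scaled by ``day_noise_scale``)."""
    items = items or list(ITEM_PARAMS)
    factors = {f: rng.normal() for f in DAY_FACTORS}
    out = {}
    for item in items:
        lg, spec, dayf = ITEM_PARAMS[item]
        v = 4.0 + active_effect * lg * traits["trait_g"]
        if spec is not None:
            v += active_effect * spec[1] * traits[f"trait_{spec[0]}"]
        if dayf is not None:
            v += day_noise_scale * dayf[1] * factors[dayf[0]]
        v += day_noise_scale * DAY_NOISE_SD * rng.normal()
        out[item] = int(np.clip(np.round(v), 1, 7))
    return out


def _generate_active(profiles: pd.DataFrame, cfg: CohortConfig,
                     rng: np.random.Generator, items: list[str]) -> pd.DataFrame:
    """Vectorized version of simulate_active_day over all user-days."""
    n_u, n_d = len(profiles), cfg.n_days
    ae, dns = cfg.effect_sizes["active"], cfg.day_noise_scale
    factors = {f: rng.normal(size=(n_u, n_d)) for f in DAY_FACTORS}
    rows = []
    for item in items:
        lg, spec, dayf = ITEM_PARAMS[item]
        v = 4.0 + ae * lg * profiles["trait_g"].to_numpy()[:, None]
        if spec is not None:
            v = v + ae * spec[1] * profiles[f"trait_{spec[0]}"].to_numpy()[:, None]
        if dayf is not None:
            v = v + dns * dayf[1] * factors[dayf[0]]
        v = v + dns * DAY_NOISE_SD * rng.normal(size=(n_u, n_d))
        vals = np.clip(np.round(v), 1, 7).astype(int)
        for j in range(n_d):
            rows.append(pd.DataFrame({
                "user_id": profiles["user_id"],
                "day": j + 1,
                "item": item,
                "value": vals[:, j],
            }))
    df = pd.concat(rows, ignore_index=True)
    return df.sort_values(["user_id", "day", "item"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mobility
# ---------------------------------------------------------------------------

def simulate_mobility_day(
    profile,
    day: int,
    severity: float,
    rng: np.random.Generator,
    passive_effect: float = 1.0,
    steps_median: float = 6000.0,
    steps_severity: float | None = None,
) -> MobilityDay:
    """Two-state GPS day (dwell at home / excursions to anchors) + steps.

    Higher severity lowers both the expected excursion count and the step
    count (``steps_severity`` overrides the severity driving steps, so
    mobility and activity can track different latent factors). Fixes snap
    to the home/anchor coordinates (event-driven significant-change
    semantics), with interpolated transit fixes."""
    if steps_severity is None:
        steps_severity = severity
    lam = float(np.exp(np.log(2.2) - 0.65 * passive_effect * severity))
    n_exc = int(min(rng.poisson(lam), 6))
    anchors = [
        (profile.school_lat, profile.school_lon),
        (profile.anchor1_lat, profile.anchor1_lon),
        (profile.anchor2_lat, profile.anchor2_lon),
    ]
    home = (profile.home_lat, profile.home_lon)

    windows = []
    for _ in range(n_exc):
        start = rng.uniform(8.0, 19.5)
        dur = rng.uniform(1.0, 3.0)
        windows.append((start, min(start + dur, 21.5), anchors[rng.integers(len(anchors))]))

    n_home = rng.poisson(10) + 2
    home_hours = np.sort(rng.uniform(0.0, 24.0, size=n_home))
    in_exc = np.zeros(len(home_hours), dtype=bool)
    for s, e, _ in windows:
        in_exc |= (home_hours >= s) & (home_hours < e)
    hours = list(home_hours[~in_exc])
    lats = [home[0]] * len(hours)
    lons = [home[1]] * len(hours)
    for s, e, (alat, alon) in windows:
        mid = (s + e) / 2.0
        # transit fix halfway, then dwell fixes at the anchor
        hours += [s, (s + mid) / 2.0, mid, e - 0.05]
        lats += [home[0], (home[0] + alat) / 2.0, alat, alat]
        lons += [home[1], (home[1] + alon) / 2.0, alon, alon]
    hours = np.asarray(hours)
    order = np.argsort(hours, kind="stable")
    steps = float(np.exp(np.log(steps_median) + 0.5 * rng.normal()
                         - 0.65 * passive_effect * steps_severity))
    return MobilityDay(hours[order], np.asarray(lats)[order], np.asarray(lons)[order],
                       steps, n_exc)


# ---------------------------------------------------------------------------
# Grid sensors
# ---------------------------------------------------------------------------

_GRID = np.arange(0, 24, 0.25)  # 96 samples/day at 15-minute intervals
_GRID_NIGHT = (_GRID >= 22.0) | (_GRID < 6.0)


def _light_day(t_ins: float, pe: float, rng: np.random.Generator, shift: float) -> np.ndarray:
    lux = np.exp(np.log(120.0) + 0.8 * rng.normal(size=len(_GRID)) + 0.1 * shift)
    night_lux = np.exp(np.log(4.0) + 0.50 * pe * t_ins + 0.8 * rng.normal(size=len(_GRID)))
    return np.where(_GRID_NIGHT, night_lux, lux)


def _brightness_day(t_ins: float, pe: float, rng: np.random.Generator) -> np.ndarray:
    day = np.clip(0.55 + 0.15 * rng.normal(size=len(_GRID)), 0, 1)
    night = np.clip(0.22 + 0.15 * pe * t_ins + 0.10 * rng.normal(size=len(_GRID)), 0, 1)
    return np.where(_GRID_NIGHT, night, day)


def _noise_day(n_exc: int, t_sdq: float, t_ed: float, pe: float,
               rng: np.random.Generator, shift: float) -> np.ndarray:
    p_out = min(0.15 * n_exc, 0.7)
    daytime = (_GRID >= 8.0) & (_GRID < 22.0)
    out = daytime & (rng.random(len(_GRID)) < p_out)
    # quieter daytime environments at higher severity (withdrawal)
    db = 33.0 - 1.5 * pe * t_sdq + 2.0 * shift \
        + 4.0 * rng.normal(size=len(_GRID)) + 14.0 * out
    night = 28.0 + 2.8 * pe * t_ed + 3.0 * rng.normal(size=len(_GRID))
    return np.where(_GRID_NIGHT, night, db)


def _battery_day(t_ed: float, t_ins: float, pe: float,
                 rng: np.random.Generator) -> np.ndarray:
    level = float(rng.uniform(45, 100))
    drain_scale = 0.45 * (1.0 + 0.65 * pe * max(t_ed, 0.0))
    # at night the phone mostly idles; insomnia severity raises the chance
    # of an active (draining) 15-minute slot
    p_night_use = float(np.clip(0.15 + 0.15 * pe * t_ins, 0.03, 0.9))
    levels = np.empty(len(_GRID))
    charging = 0
    for i in range(len(_GRID)):
        if charging > 0:
            level = min(100.0, level + 9.0)
            charging -= 1
        else:
            active = (not _GRID_NIGHT[i]) or (rng.random() < p_night_use)
            if active:
                level -= rng.exponential(drain_scale)
            if level < 12.0 and rng.random() < 0.5:
                charging = int(rng.integers(4, 9))
            level = max(0.0, level)
        levels[i] = level
    return np.round(levels, 1)


def _app_events_day(g: float, t_si: float, pe: float, rng: np.random.Generator):
    n = rng.poisson(np.exp(np.log(22.0) + 0.10 * pe * g))
    if n == 0:
        return None
    base = np.array([0.04, 0.22, 0.15, 0.08, 0.05, 0.03, 0.08, 0.05, 0.10, 0.20])
    w = base.copy()
    w[2] *= np.exp(0.7 * pe * t_si)  # entertainment share grows with ideation severity
    w /= w.sum()
    cats = rng.choice(len(APP_CATEGORIES), size=n, p=w)
    # events cluster in waking/evening hours, with a night tail
    hours = np.concatenate([
        rng.uniform(7.0, 22.0, size=int(np.ceil(n * 0.85))),
        rng.uniform(22.0, 26.0, size=n - int(np.ceil(n * 0.85))),
    ])[:n] % 24.0
    durations = np.exp(np.log(90.0) + 0.55 * pe * t_si + 0.7 * rng.normal(size=n))
    app_ids = np.array([f"{APP_CATEGORIES[c]}_{rng.integers(3)}" for c in cats])
    return hours, app_ids, np.array([APP_CATEGORIES[c] for c in cats]), durations


def _mindcraft_day(t_ins: float, pe: float, rng: np.random.Generator):
    n = 1 + rng.poisson(0.8)
    starts = list(rng.uniform(7.0, 21.9, size=n))
    if rng.random() < np.clip(0.15 + 0.18 * pe * t_ins, 0.0, 0.6):
        starts.append(float(rng.uniform(22.0, 24.0) % 24.0))
    starts = np.sort(np.asarray(starts))
    ends = starts + rng.uniform(2.0, 10.0, size=len(starts)) / 60.0
    return starts, ends


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _generate_profiles(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_users
    traits = _draw_traits(n, rng)
    platform = np.where(rng.random(n) < cfg.ios_fraction, "ios", "android")
    sex = rng.choice(["female", "male", "other"], size=n, p=[0.71, 0.25, 0.04])
    site = rng.choice(_SITES, size=n)
    lat_shift = 0.05 * cfg.site_shift
    homes_lat, homes_lon = [], []
    school_lat, school_lon = [], []
    for s in site:
        clat, clon = _SITE_CENTERS[s]
        homes_lat.append(clat + lat_shift + rng.normal(0, 0.03))
        homes_lon.append(clon + lat_shift + rng.normal(0, 0.03))
        school_lat.append(clat + lat_shift)
        school_lon.append(clon + lat_shift)
    prof = pd.DataFrame({
        "user_id": [f"u{i:04d}" for i in range(n)],
        "platform": platform,
        "sex": sex,
        "site": site,
        "home_lat": homes_lat,
        "home_lon": homes_lon,
        "school_lat": school_lat,
        "school_lon": school_lon,
    })
    prof["anchor1_lat"] = prof["home_lat"] + rng.normal(0, 0.02, size=n)
    prof["anchor1_lon"] = prof["home_lon"] + rng.normal(0, 0.02, size=n)
    prof["anchor2_lat"] = prof["home_lat"] + rng.normal(0, 0.02, size=n)
    prof["anchor2_lon"] = prof["home_lon"] + rng.normal(0, 0.02, size=n)
    # before missingness every platform-compatible sensor is "enabled"
    enabled = []
    for p in platform:
        cats = available_categories(p, set(SENSOR_CATEGORIES))
        enabled.append(";".join(sorted(cats)))
    prof["enabled_sensors"] = enabled
    for c in traits.columns:
        prof[c] = traits[c].to_numpy()
    return prof


def _generate_sensors(profiles: pd.DataFrame, cfg: CohortConfig,
                      rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    pe = cfg.effect_sizes["passive"]
    shift = cfg.site_shift
    logs: dict[str, list] = {c: [] for c in SENSOR_CATEGORIES}
    a = GENERAL_FACTOR_WEIGHT
    b = np.sqrt(1.0 - a ** 2)
    for prof in profiles.itertuples(index=False):
        compatible = available_categories(prof.platform, set(SENSOR_CATEGORIES))
        # passive behaviour tracks the outcome traits directly; the
        # self-report items carry (almost) only the general factor, so the
        # outcome-specific trait components reach the features through the
        # passive streams alone
        spec = {k: getattr(prof, f"trait_{k}") for k in ("sdq", "ins", "si", "ed")}
        for day in range(1, cfg.n_days + 1):
            mob_sev = 0.4 * prof.trait_g + 0.3 * spec["si"] + 0.3 * spec["sdq"]
            mob = simulate_mobility_day(prof, day, mob_sev, rng, pe, cfg.steps_median,
                                        steps_severity=spec["sdq"])
            if "location" in compatible:
                logs["location"].append(pd.DataFrame({
                    "user_id": prof.user_id, "day": day,
                    "hour": mob.hours, "lat": mob.lats, "lon": mob.lons,
                }))
            if "step_count" in compatible:
                logs["step_count"].append(pd.DataFrame({
                    "user_id": [prof.user_id], "day": [day],
                    "steps": [round(mob.steps)],
                }))
            if "battery" in compatible:
                logs["battery"].append(pd.DataFrame({
                    "user_id": prof.user_id, "day": day, "hour": _GRID,
                    "level": _battery_day(spec["ed"], spec["ins"], pe, rng),
                }))
            if "ambient_light" in compatible:
                logs["ambient_light"].append(pd.DataFrame({
                    "user_id": prof.user_id, "day": day, "hour": _GRID,
                    "lux": np.round(_light_day(spec["ins"], pe, rng, shift), 2),
                }))
            if "noise" in compatible:
                logs["noise"].append(pd.DataFrame({
                    "user_id": prof.user_id, "day": day, "hour": _GRID,
                    "db": np.round(_noise_day(mob.n_excursions, spec["sdq"], spec["ed"], pe, rng, shift), 2),
                }))
            if "screen_brightness" in compatible:
                logs["screen_brightness"].append(pd.DataFrame({
                    "user_id": prof.user_id, "day": day, "hour": _GRID,
                    "value": np.round(_brightness_day(spec["ins"], pe, rng), 3),
                }))
            if "app_usage" in compatible:
                ev = _app_events_day(prof.trait_g, spec["si"], pe, rng)
                if ev is not None:
                    h, ids, cats, dur = ev
                    logs["app_usage"].append(pd.DataFrame({
                        "user_id": prof.user_id, "day": day, "hour": np.round(h, 3),
                        "app_id": ids, "category": cats,
                        "duration_s": np.round(dur, 1),
                    }))
            if "mindcraft_usage" in compatible:
                s, e = _mindcraft_day(spec["ins"], pe, rng)
                logs["mindcraft_usage"].append(pd.DataFrame({
                    "user_id": prof.user_id, "day": day,
                    "start_hour": np.round(s, 3), "end_hour": np.round(e, 3),
                }))
    out = {}
    for cat, frames in logs.items():
        if frames:
            out[cat] = pd.concat(frames, ignore_index=True)
        else:
            out[cat] = pd.DataFrame()
    return out


def apply_missingness(cohort: Cohort, config: CohortConfig,
                      rng: np.random.Generator) -> Cohort:
    """Impose engagement decay and sensor opt-in on a complete cohort.

    Active responses follow a geometric dropout: day 1 is always answered
    and the per-day continuation probability is calibrated so the expected
    fraction of users still responding on the final day equals
    ``active_retention_final``. Passive enablement is static: a configurable
    fraction of users enable no sensors at all; the rest enable each
    platform-compatible sensor with its opt-in rate."""
    n_days = config.n_days
    retention = config.active_retention_final
    profiles = cohort.profiles.copy()
    n = len(profiles)

    if retention >= 1.0:
        dropout_day = np.full(n, np.iinfo(np.int64).max)
    else:
        q = retention ** (1.0 / (n_days - 1))
        dropout_day = rng.geometric(1.0 - q, size=n)  # last answered day
    active = cohort.active
    last_day = pd.Series(dropout_day, index=profiles["user_id"].to_numpy())
    keep = active["day"].to_numpy() <= last_day.loc[active["user_id"]].to_numpy()
    active = active.loc[keep].reset_index(drop=True)

    zero = rng.random(n) < config.zero_sensor_fraction
    enabled_final = []
    for i, prof in enumerate(profiles.itertuples(index=False)):
        if zero[i]:
            enabled_final.append("")
            continue
        compatible = available_categories(prof.platform, set(SENSOR_CATEGORIES))
        kept = {c for c in sorted(compatible)
                if rng.random() < config.sensor_optin_rates.get(c, 0.0)}
        enabled_final.append(";".join(sorted(kept)))
    profiles["enabled_sensors"] = enabled_final

    sensors = {}
    enabled_map = dict(zip(profiles["user_id"], enabled_final))
    for cat, df in cohort.sensors.items():
        if len(df) == 0:
            sensors[cat] = df
            continue
        users_with = {u for u, e in enabled_map.items() if cat in e.split(";")}
        sensors[cat] = df[df["user_id"].isin(users_with)].reset_index(drop=True)

    return Cohort(profiles=profiles, outcomes=cohort.outcomes, active=active,
                  sensors=sensors, config=config, active_items=list(cohort.active_items))


def generate_cohort(config: CohortConfig, apply_missing: bool = True) -> Cohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles = _generate_profiles(config, rng)
    outcomes = _outcome_scores(profiles, config.prevalences, rng)
    outcomes.insert(0, "user_id", profiles["user_id"].to_numpy())
    items = list(ITEM_PARAMS)
    active = _generate_active(profiles, config, rng, items)
    if any(config.sensor_optin_rates.get(c, 0.0) > 0 for c in SENSOR_CATEGORIES):
        sensors = _generate_sensors(profiles, config, rng)
    else:
        sensors = {c: pd.DataFrame() for c in SENSOR_CATEGORIES}
    cohort = Cohort(profiles=profiles, outcomes=outcomes, active=active,
                    sensors=sensors, config=config, active_items=items)
    if apply_missing:
        cohort = apply_missingness(cohort, config, rng)
    return cohort


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_MANDATORY = {
    "profiles.csv": ["user_id", "platform", "sex", "site", "home_lat", "home_lon", "enabled_sensors"],
    "outcomes.csv": ["user_id", "sdq_total", "sci_total", "ed15_total", "si_frequency"],
    "active.csv": ["user_id", "day", "item", "value"],
}


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write a cohort as delimited-text tables plus a JSON manifest."""
    directory = Path(directory)
    (directory / "sensors").mkdir(parents=True, exist_ok=True)
    cohort.profiles.to_csv(directory / "profiles.csv", index=False)
    cohort.outcomes.to_csv(directory / "outcomes.csv", index=False)
    cohort.active.to_csv(directory / "active.csv", index=False)
    for cat, df in cohort.sensors.items():
        df.to_csv(directory / "sensors" / f"{cat}.csv", index=False)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": cohort.config.seed,
        "config": cohort.config.to_dict(),
        "active_items": cohort.active_items,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(directory: str | Path) -> Cohort:
    """Load a cohort written by :func:`write_cohort` (round-trip identity)."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = CohortConfig.from_dict(manifest["config"])
    if manifest.get("seed") != config.seed:
        logger.warning("manifest seed %r does not match config seed %r; loading anyway",
                       manifest.get("seed"), config.seed)
        warnings.warn("manifest seed mismatch with config; data loaded anyway")

    tables = {}
    for fname, cols in _MANDATORY.items():
        path = directory / fname
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001
            raise ParseError(f"{path}: failed to parse ({exc})") from exc
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: line 1: missing mandatory column(s) {missing}")
        tables[fname] = df
    profiles = tables["profiles.csv"]
    profiles["enabled_sensors"] = profiles["enabled_sensors"].fillna("")
    sensors = {}
    for cat in SENSOR_CATEGORIES:
        path = directory / "sensors" / f"{cat}.csv"
        if path.exists():
            try:
                sensors[cat] = pd.read_csv(path)
            except pd.errors.EmptyDataError:
                sensors[cat] = pd.DataFrame()
        else:
            sensors[cat] = pd.DataFrame()
    return Cohort(profiles=profiles, outcomes=tables["outcomes.csv"],
                  active=tables["active.csv"], sensors=sensors, config=config,
                  active_items=list(manifest.get("active_items", list(ITEM_PARAMS))))
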