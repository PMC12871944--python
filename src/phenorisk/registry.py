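"""Registry of the 92 engineered passive-sensor features.

Eight sensor categories contribute a fixed number of daily features each:
ambient light 8, app usage 36, background noise 10, battery 8, location 15,
Mindcraft (in-app) usage 3, screen brightness 8, step count 4. Ambient
light, app usage, and background noise are collectible on Android only;
screen brightness on iOS only; the rest on both platforms.

Two published feature lists under-enumerate their categories (app usage
names ~30 of 36, location 13 plus one extra named in running text); the
gap is closed with semantically adjacent fillers that are flagged
``filler=True`` here so downstream reports can distinguish them.
"""

from __future__ import annotations

from dataclasses import dataclass

SENSOR_CATEGORIES = (
    "ambient_light",
    "app_usage",
    "noise",
    "battery",
    "location",
    "mindcraft_usage",
    "screen_brightness",
    "step_count",
)

#: category -> number of daily features engineered from it
CATEGORY_COUNTS = {
    "ambient_light": 8,
    "app_usage": 36,
    "noise": 10,
    "battery": 8,
    "location": 15,
    "mindcraft_usage": 3,
    "screen_brightness": 8,
    "step_count": 4,
}

ANDROID_ONLY = frozenset({"ambient_light", "app_usage", "noise"})
IOS_ONLY = frozenset({"screen_brightness"})

APP_CATEGORIES = (
    "camera",
    "communication",
    "entertainment",
    "gaming",
    "physical_health",
    "mental_health",
    "mindcraft",
    "news",
    "productivity",
    "social_media",
)


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    category: str
    window: str  # "day" | "night" | "full"
    kind: str  # "continuous" | "binary"
    units: str
    filler: bool = False


def _reading_specs(prefix: str, category: str, units: str, with_max: bool) -> list[FeatureSpec]:
    stats = ["total", "mean", "median", "max", "sd"] if with_max else ["total", "mean", "median", "sd"]
    specs = []
    for window in ("day", "night"):
        for stat in stats:
            specs.append(FeatureSpec(f"{prefix}_{stat}_{window}", category, window, "continuous", units))
    return specs


def feature_registry() -> list[FeatureSpec]:
    """Ordered list of the 92 passive FeatureSpec entries."""
    specs: list[FeatureSpec] = []

    specs += _reading_specs("light", "ambient_light", "lux", with_max=False)

    # app usage: 5 day stats, 5 night stats, 10 category times, 10 category
    # shares, 6 fillers
    for window in ("day", "night"):
        specs += [
            FeatureSpec(f"app_count_{window}", "app_usage", window, "continuous", "events"),
            FeatureSpec(f"app_unique_{window}", "app_usage", window, "continuous", "apps"),
            FeatureSpec(f"app_total_time_{window}", "app_usage", window, "continuous", "s"),
            FeatureSpec(f"app_mean_time_{window}", "app_usage", window, "continuous", "s"),
            FeatureSpec(f"app_median_time_{window}", "app_usage", window, "continuous", "s"),
        ]
    for cat in APP_CATEGORIES:
        specs.append(FeatureSpec(f"app_cat_{cat}_time", "app_usage", "full", "continuous", "s"))
    for cat in APP_CATEGORIES:
        specs.append(FeatureSpec(f"app_cat_{cat}_pct", "app_usage", "full", "continuous", "%"))
    specs += [
        FeatureSpec("app_sd_time_day", "app_usage", "day", "continuous", "s", filler=True),
        FeatureSpec("app_sd_time_night", "app_usage", "night", "continuous", "s", filler=True),
        FeatureSpec("app_first_hour", "app_usage", "full", "continuous", "h", filler=True),
        FeatureSpec("app_last_hour", "app_usage", "full", "continuous", "h", filler=True),
        FeatureSpec("app_unique_cats_day", "app_usage", "day", "continuous", "categories", filler=True),
        FeatureSpec("app_unique_cats_night", "app_usage", "night", "continuous", "categories", filler=True),
    ]

    specs += _reading_specs("noise", "noise", "dB", with_max=True)

    specs += [
        FeatureSpec("battery_level_min", "battery", "full", "continuous", "%"),
        FeatureSpec("battery_level_max", "battery", "full", "continuous", "%"),
        FeatureSpec("battery_level_mean", "battery", "full", "continuous", "%"),
        FeatureSpec("battery_level_median", "battery", "full", "continuous", "%"),
        FeatureSpec("battery_charge_count", "battery", "full", "continuous", "charges"),
        FeatureSpec("battery_drain_per_hour", "battery", "full", "continuous", "%/h"),
        FeatureSpec("battery_hours_below_20", "battery", "full", "continuous", "h"),
        FeatureSpec("battery_night_usage_count", "battery", "night", "continuous", "readings"),
    ]

    specs += [
        FeatureSpec("loc_mean_lat", "location", "full", "continuous", "deg"),
        FeatureSpec("loc_mean_lon", "location", "full", "continuous", "deg"),
        FeatureSpec("loc_total_distance", "location", "full", "continuous", "m"),
        FeatureSpec("loc_fix_count", "location", "full", "continuous", "fixes"),
        FeatureSpec("loc_max_dist_home", "location", "full", "continuous", "m"),
        FeatureSpec("loc_mean_dist_home", "location", "full", "continuous", "m"),
        FeatureSpec("loc_median_dist_home", "location", "full", "continuous", "m"),
        FeatureSpec("loc_night_movement", "location", "night", "continuous", "m"),
        FeatureSpec("loc_radius_gyration", "location", "full", "continuous", "m"),
        FeatureSpec("loc_sd_lat", "location", "full", "continuous", "deg"),
        FeatureSpec("loc_sd_lon", "location", "full", "continuous", "deg"),
        FeatureSpec("loc_entropy", "location", "full", "continuous", "nats"),
        FeatureSpec("loc_time_at_home", "location", "full", "continuous", "fraction"),
        FeatureSpec("loc_max_dist_centroid", "location", "full", "continuous", "m"),
        FeatureSpec("loc_entropy_normalized", "location", "full", "continuous", "fraction", filler=True),
    ]

    specs += [
        FeatureSpec("mindcraft_first_hour", "mindcraft_usage", "full", "continuous", "h"),
        FeatureSpec("mindcraft_last_hour", "mindcraft_usage", "full", "continuous", "h"),
        FeatureSpec("mindcraft_night_count", "mindcraft_usage", "night", "continuous", "sessions"),
    ]

    specs += _reading_specs("brightness", "screen_brightness", "fraction", with_max=False)

    specs += [
        FeatureSpec("steps_count", "step_count", "full", "continuous", "steps"),
        FeatureSpec("steps_gt_5000", "step_count", "full", "binary", ""),
        FeatureSpec("steps_gt_7500", "step_count", "full", "binary", ""),
        FeatureSpec("steps_gt_10000", "step_count", "full", "binary", ""),
    ]

    names = [s.name for s in specs]
    assert len(names) == len(set(names)) == 92
    return specs


def specs_by_category(registry: list[FeatureSpec] | None = None) -> dict[str, list[FeatureSpec]]:
    registry = registry or feature_registry()
    out: dict[str, list[FeatureSpec]] = {c: [] for c in SENSOR_CATEGORIES}
    for spec in registry:
        out[spec.category].append(spec)
    return out


def available_categories(platform: str, enabled: set[str] | frozenset[str]) -> set[str]:
    """Sensor categories that can actually produce data for one user.

    Platform gating removes Android-only categories on iOS and vice versa,
    regardless of what the user opted in to.
    """
    if platform == "ios":
        blocked = ANDROID_ONLY
    elif platform == "android":
        blocked = IOS_ONLY
    else:
        raise ValueError(f"unknown platform {platform!r}")
    return {c for c in enabled if c in SENSOR_CATEGORIES and c not in blocked}
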