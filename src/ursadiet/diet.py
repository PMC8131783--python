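"""Scat-based diet quantification.

Turns raw scat observations (point-frame counts or visually estimated
percent fecal volumes, vFV) into corrected diet compositions:

* occupancy — the share of grid intersections covered by each food item,
  used as the volumetric proportion of that item in the scat;
* EDC — estimated dietary content: fecal volumes weighted by dry-matter
  correction factors (CF_D) and renormalized, approximating the
  composition of the ingested dry mass;
* EDEC — estimated digestible-energy content: EDC weights further
  multiplied by digestible-energy correction factors (CF_E).

Correction factors compensate for differential digestibility: highly
digestible items (salmon, mammals) are under-represented in feces and
carry CF_D > 1 relative to poorly digestible ones. Nonfood items
(incidentally ingested twigs, debris, grooming hair) are excluded before
EDC/EDEC are computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

#: The nine food categories used for reporting, plus the nonfood bucket.
CATEGORIES = (
    "plants",
    "pine_nuts",
    "drupes",
    "berries",
    "acorns_nuts",
    "insects",
    "mammals",
    "salmon",
    "other",
)
NONFOOD = "nonfood"

#: Study months (June–October) and their numbers.
MONTHS = {"June": 6, "July": 7, "August": 8, "September": 9, "October": 10}
MONTH_NAMES = {v: k for k, v in MONTHS.items()}

#: Bear hair at or below this mean volumetric share per scat is treated as
#: grooming residue (nonfood); above it, as conspecific consumption.
BEAR_HAIR_THRESHOLD = 0.5

#: Point-frame acceptance thresholds.
MIN_POINTS = 200
MIN_SALMON_WET_WEIGHT_G = 50.0


class DegenerateInputError(ValueError):
    """An input with no usable signal (all-zero counts, zero food volume)."""


class ConfigurationError(ValueError):
    """Inconsistent taxonomy/configuration (missing CF, unknown category...)."""


@dataclass(frozen=True)
class FoodItemTable:
    """Item taxonomy: category membership, correction factors, hair flag.

    Parameters
    ----------
    category : mapping item_id -> category name (one of ``CATEGORIES`` or
        ``"nonfood"``).
    cf_d : mapping item_id -> dry-matter correction factor (dimensionless,
        > 0). May omit nonfood items.
    cf_e : mapping item_id -> digestible-energy correction factor.
    bear_hair : set of item_ids that are bear hair.
    """

    category: dict
    cf_d: dict
    cf_e: dict
    bear_hair: frozenset = frozenset()

    def __post_init__(self):
        valid = set(CATEGORIES) | {NONFOOD}
        for item, cat in self.category.items():
            if cat not in valid:
                raise ConfigurationError(f"item {item!r}: unknown category {cat!r}")
        for name, cf in (("cf_d", self.cf_d), ("cf_e", self.cf_e)):
            for item, value in cf.items():
                if not (math.isfinite(value) and value > 0):
                    raise ConfigurationError(f"{name}[{item!r}] = {value}: must be finite and > 0")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FoodItemTable":
        """Build from a taxonomy table with columns
        item_id, category, cf_d, cf_e, is_bear_hair."""
        required = {"item_id", "category", "cf_d", "cf_e"}
        missing = required - set(frame.columns)
        if missing:
            raise ConfigurationError(f"taxonomy missing columns: {sorted(missing)}")
        hair = frozenset(
            frame.loc[frame.get("is_bear_hair", False).astype(bool), "item_id"]
        ) if "is_bear_hair" in frame.columns else frozenset()
        return cls(
            category=dict(zip(frame["item_id"], frame["category"])),
            cf_d={r.item_id: r.cf_d for r in frame.itertuples() if math.isfinite(r.cf_d)},
            cf_e={r.item_id: r.cf_e for r in frame.itertuples() if math.isfinite(r.cf_e)},
            bear_hair=hair,
        )

    def is_nonfood_category(self, item: str) -> bool:
        return self.category.get(item) == NONFOOD

    def category_of(self, item: str) -> str:
        try:
            return self.category[item]
        except KeyError:
            raise ConfigurationError(f"item {item!r} has no category in the taxonomy")


@dataclass(frozen=True)
class ScatRecord:
    """One scat: identity, collection period, and measured composition.

    ``point_counts`` (point-frame method) or ``vfv`` (visual method) is
    present, never both. ``half`` is the semimonthly assignment (early =
    day-of-month <= 15); scats of unknown day are excluded from
    semimonthly, but not monthly, summaries.
    """

    scat_id: str
    year: int
    month: int
    method: str  # "point_frame" | "visual"
    half: str = "unknown"  # "early" | "late" | "unknown"
    point_counts: dict | None = None
    vfv: dict | None = None
    wet_weight_g: float = float("nan")

    def __post_init__(self):
        if self.method not in ("point_frame", "visual"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "point_frame":
            if self.point_counts is None or self.vfv is not None:
                raise ValueError("point_frame record must carry point_counts only")
            for item, c in self.point_counts.items():
                if c < 0 or int(c) != c:
                    raise ValueError(f"count for {item!r} must be a non-negative integer")
        else:
            if self.vfv is None or self.point_counts is not None:
                raise ValueError("visual record must carry vfv only")
            total = sum(self.vfv.values())
            if abs(total - 100.0) > 0.5:
                raise ValueError(f"vfv sums to {total:.2f}, expected 100 +/- 0.5")
        if self.half not in ("early", "late", "unknown"):
            raise ValueError(f"unknown half {self.half!r}")


@dataclass(frozen=True)
class DietProfile:
    """A percent composition over items or over the nine categories.

    ``nonfood_items`` is populated once :func:`apply_nonfood_rules` has
    resolved which items of this particular scat count as nonfood (the
    bear-hair rule is per-scat, so the set is profile-specific).
    """

    basis: str  # "occupancy" | "vfv" | "edc" | "edec"
    level: str  # "item" | "category"
    values: dict
    nonfood_items: frozenset | None = None

    def food_values(self) -> dict:
        nf = self.nonfood_items or frozenset()
        return {k: v for k, v in self.values.items() if k not in nf}

    def total(self) -> float:
        return sum(self.values.values())


@dataclass(frozen=True)
class Acceptance:
    accepted: bool
    reason: str


@dataclass(frozen=True)
class YearClass:
    pine_high: bool
    salmon_high: bool

    @property
    def diet1(self) -> bool:
        """High consumption of both pine nuts and salmon."""
        return self.pine_high and self.salmon_high

    @property
    def diet2(self) -> bool:
        """Low consumption of both pine nuts and salmon."""
        return not self.pine_high and not self.salmon_high


@dataclass(frozen=True)
class YearClassification:
    years: dict  # year -> YearClass
    pine_mean: float
    salmon_mean: float

    def diet1_years(self) -> set:
        return {y for y, c in self.years.items() if c.diet1}

    def diet2_years(self) -> set:
        return {y for y, c in self.years.items() if c.diet2}


def compute_occupancy(point_counts: dict) -> DietProfile:
    """Occupancy_i [%] = 100 x count_i / total count, over all counted items."""
    total = sum(point_counts.values())
    if total <= 0:
        raise DegenerateInputError("all point counts are zero")
    values = {item: 100.0 * c / total for item, c in point_counts.items()}
    return DietProfile(basis="occupancy", level="item", values=values)


def accept_scat(record: ScatRecord, taxonomy: FoodItemTable) -> Acceptance:
    """Point-frame acceptance: >= 200 points, or the salmon exception.

    Salmon is so digestible that washed salmon scats rarely yield 200
    countable points; scats containing salmon are accepted at any count
    provided the sample's wet weight is >= 50 g.
    """
    if record.method != "point_frame":
        raise ValueError("acceptance applies to point-frame records only")
    counts = record.point_counts
    total = sum(counts.values())
    if total >= MIN_POINTS:
        return Acceptance(True, f"total points {total} >= {MIN_POINTS}")
    has_salmon = any(
        c > 0 and taxonomy.category.get(item) == "salmon" for item, c in counts.items()
    )
    if has_salmon and record.wet_weight_g >= MIN_SALMON_WET_WEIGHT_G:
        return Acceptance(
            True,
            f"salmon present and wet weight {record.wet_weight_g:.0f} g >= "
            f"{MIN_SALMON_WET_WEIGHT_G:.0f} g",
        )
    if has_salmon:
        return Acceptance(
            False,
            f"total points {total} < {MIN_POINTS} and wet weight "
            f"{record.wet_weight_g:.0f} g < {MIN_SALMON_WET_WEIGHT_G:.0f} g",
        )
    return Acceptance(False, f"total points {total} < {MIN_POINTS}")


def apply_nonfood_rules(profile: DietProfile, taxonomy: FoodItemTable) -> DietProfile:
    """Resolve this scat's nonfood set.

    Items of nonfood category are always nonfood. Bear-hair items are
    nonfood (grooming residue) when their share is <= 0.5%, food
    (conspecific consumption) otherwise.
    """
    if profile.level != "item":
        raise ValueError("nonfood rules apply to item-level profiles")
    nonfood = set()
    for item, value in profile.values.items():
        if taxonomy.is_nonfood_category(item):
            nonfood.add(item)
        elif item in taxonomy.bear_hair and value <= BEAR_HAIR_THRESHOLD:
            nonfood.add(item)
    return replace(profile, nonfood_items=frozenset(nonfood))


def _corrected_profile(profile, taxonomy, weight_of, basis) -> DietProfile:
    if profile.basis not in ("occupancy", "vfv"):
        raise ValueError(f"cannot correct a profile on basis {profile.basis!r}")
    if profile.nonfood_items is None:
        raise ValueError("apply_nonfood_rules before computing corrected content")
    weights = {}
    for item, v in profile.food_values().items():
        if v == 0:
            continue
        try:
            weights[item] = weight_of(item, v)
        except KeyError as exc:
            raise ConfigurationError(
                f"no correction factor for food item {item!r}"
            ) from exc
    total = sum(weights.values())
    if total <= 0:
        raise DegenerateInputError("zero total food volume after nonfood exclusion")
    values = {item: 100.0 * w / total for item, w in weights.items()}
    return DietProfile(basis=basis, level="item", values=values,
                       nonfood_items=profile.nonfood_items)


def compute_edc(profile: DietProfile, taxonomy: FoodItemTable) -> DietProfile:
    """EDC_i = 100 * V_i CF_D,i / sum_food V_j CF_D,j (food items only)."""
    return _corrected_profile(
        profile, taxonomy, lambda item, v: v * taxonomy.cf_d[item], "edc"
    )


def compute_edec(profile: DietProfile, taxonomy: FoodItemTable,
                 weight=None) -> DietProfile:
    """EDEC_i = 100 * V_i CF_D,i CF_E,i / sum_food V_j CF_D,j CF_E,j.

    The weighting (volume -> dry matter via CF_D, then -> digestible
    energy via CF_E) is the composition-then-energy convention; pass
    ``weight(v, cf_d, cf_e)`` to override it.
    """
    if weight is None:
        weight = lambda v, cf_d, cf_e: v * cf_d * cf_e
    return _corrected_profile(
        profile, taxonomy,
        lambda item, v: weight(v, taxonomy.cf_d[item], taxonomy.cf_e[item]),
        "edec",
    )


def aggregate_categories(profile: DietProfile, taxonomy: FoodItemTable) -> DietProfile:
    """Sum item values into the nine reporting categories (plus nonfood)."""
    if profile.level != "item":
        raise ValueError("profile is already at category level")
    out: dict = {}
    for item, v in profile.values.items():
        nf = profile.nonfood_items or frozenset()
        cat = NONFOOD if item in nf else taxonomy.category_of(item)
        out[cat] = out.get(cat, 0.0) + v
    return DietProfile(basis=profile.basis, level="category", values=out)


def summarize_period(records, profiles, grouping: str = "month") -> pd.DataFrame:
    """Per-period mean profile, percent frequency of occurrence, and n.

    Parameters
    ----------
    records : sequence of ScatRecord
    profiles : sequence of DietProfile aligned with ``records``, all on
        the same basis/level.
    grouping : "month" | "semimonth" | "year_month"

    Returns a tidy frame with columns group, key, mean, fo, n. The group
    mean is the unweighted arithmetic mean of per-scat percent profiles
    (each scat is the sampling unit); FO_i is the percent of scats in the
    group with a positive value for key i.
    """
    if len(records) != len(profiles):
        raise ValueError("records and profiles must align")
    groups: dict = {}
    for rec, prof in zip(records, profiles):
        if grouping == "month":
            key = (rec.month,)
        elif grouping == "semimonth":
            if rec.half == "unknown":
                continue
            key = (rec.month, rec.half)
        elif grouping == "year_month":
            key = (rec.year, rec.month)
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        groups.setdefault(key, []).append(prof)

    rows = []
    for key in sorted(groups, key=str):
        profs = groups[key]
        n = len(profs)
        if n == 0:  # pragma: no cover - empty groups never materialize
            logger.warning("empty group %s omitted", key)
            continue
        keys = sorted({k for p in profs for k in p.values})
        for k in keys:
            vals = [p.values.get(k, 0.0) for p in profs]
            rows.append({
                "group": "/".join(str(part) for part in key),
                "key": k,
                "mean": sum(vals) / n,
                "fo": 100.0 * sum(v > 0 for v in vals) / n,
                "n": n,
            })
    return pd.DataFrame(rows, columns=["group", "key", "mean", "fo", "n"])


def format_percent(value: float) -> str:
    """Render a percent contribution: em-dash for exact zero, ``tr``
    (trace) for positive values below 0.05, otherwise one decimal."""
    if value == 0:
        return "—"
    if 0 < value < 0.05:
        return "tr"
    return f"{value:.1f}"


def classify_years(august_pine_edc: dict, september_salmon_edc: dict) -> YearClassification:
    """High/low consumption-year labels from annual EDC values.

    A year is pine-high (salmon-high) when its August pine-nut
    (September salmon) EDC strictly exceeds the mean over all study
    years. diet1 = high both; diet2 = low both.
    """
    if set(august_pine_edc) != set(september_salmon_edc):
        raise ConfigurationError("pine and salmon year sets differ")
    if len(august_pine_edc) < 2:
        raise ConfigurationError("need at least two years to classify")
    pine_mean = sum(august_pine_edc.values()) / len(august_pine_edc)
    salmon_mean = sum(september_salmon_edc.values()) / len(september_salmon_edc)
    years = {
        y: YearClass(
            pine_high=august_pine_edc[y] > pine_mean,
            salmon_high=september_salmon_edc[y] > salmon_mean,
        )
        for y in august_pine_edc
    }
    return YearClassification(years=years, pine_mean=pine_mean, salmon_mean=salmon_mean)
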