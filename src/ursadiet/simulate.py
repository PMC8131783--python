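"""Synthetic-study generator with known ground truth.

Emulates the field study's two data streams so every pipeline stage can
be exercised end to end:

* scats — per month-year "true" ingested compositions drawn from a
  Dirichlet around seasonal mean diets, distorted into expected fecal
  compositions by dividing by the dry-matter correction factors
  (the exact inverse of the EDC computation), then counted with
  multinomial point-frame noise;
* photographs — per bear-session true TH:HTL values from smooth
  seasonal log-scale trajectories (different for high- and
  low-consumption years), a reproductive-status offset, crossed
  year/bear random intercepts, and gamma photo-level noise; landmark
  coordinates are constructed so the measurement routine returns the
  drawn ratio (exactly, when replicate jitter is zero), then rotated by
  a random ground angle.

Default parameter values reproduce the study's conditions: seasonal
mean diets follow the published monthly EDC table, August pine-nut and
September salmon shares vary by year around the published high/low
values, scat counts per month-year match the published sample sizes,
and the condition model uses a -0.025 log-scale offset for females with
dependent young.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .condition import SESSIONS
from .diet import CATEGORIES, ScatRecord, FoodItemTable

__all__ = ["StudyConfig", "example_taxonomy", "gen_diet", "gen_condition", "gen_study"]


def _default_items():
    """Example item taxonomy. The correction factors are placeholders in
    literature-plausible ranges (digestible items carry larger CF_D);
    they are NOT the study's appendix values, which must be supplied by
    the user for real analyses."""
    rows = [
        # item_id, category, cf_d, cf_e, hair, within-category weight
        ("herbaceous_plants", "plants", 1.0, 0.55, False, 0.92),
        ("woody_plants", "plants", 1.0, 0.55, False, 0.08),
        ("pine_nuts", "pine_nuts", 1.5, 1.35, False, 1.0),
        ("prunus_drupes", "drupes", 1.2, 0.95, False, 1.0),
        ("vitis_berries", "berries", 1.2, 1.00, False, 0.6),
        ("actinidia_berries", "berries", 1.2, 1.00, False, 0.4),
        ("quercus_acorns", "acorns_nuts", 1.6, 1.20, False, 1.0),
        ("formicidae", "insects", 1.1, 1.60, False, 1.0),
        ("cervus_deer", "mammals", 2.5, 1.80, False, 0.95),
        ("ursus_hair", "mammals", 2.5, 1.80, True, 0.05),
        ("salmon", "salmon", 6.0, 1.15, False, 1.0),
        ("fungi", "other", 1.0, 0.80, False, 1.0),
        ("debris", "nonfood", float("nan"), float("nan"), False, 0.0),
    ]
    return pd.DataFrame(
        rows, columns=["item_id", "category", "cf_d", "cf_e", "is_bear_hair", "weight"]
    )


def example_taxonomy() -> pd.DataFrame:
    """The example taxonomy table (see :func:`_default_items`)."""
    return _default_items().drop(columns="weight")


#: Seasonal mean true diets (ingested/EDC scale, percent by category),
#: following the published monthly values.
_MONTH_PROFILES = {
    6: {"plants": 76.4, "pine_nuts": 0.0, "drupes": 0.0, "berries": 0.3,
        "acorns_nuts": 6.7, "insects": 6.3, "mammals": 6.9, "salmon": 0.0,
        "other": 3.4},
    7: {"plants": 47.7, "pine_nuts": 2.8, "drupes": 6.9, "berries": 2.4,
        "acorns_nuts": 5.2, "insects": 24.6, "mammals": 3.0, "salmon": 0.1,
        "other": 7.2},
    8: {"plants": 24.7, "pine_nuts": 34.9, "drupes": 6.6, "berries": 4.2,
        "acorns_nuts": 0.9, "insects": 12.1, "mammals": 0.5, "salmon": 12.2,
        "other": 4.0},
    9: {"plants": 5.3, "pine_nuts": 7.0, "drupes": 8.2, "berries": 15.2,
        "acorns_nuts": 19.6, "insects": 0.3, "mammals": 0.2, "salmon": 44.2,
        "other": 0.1},
    10: {"plants": 2.4, "pine_nuts": 0.0, "drupes": 0.3, "berries": 31.8,
         "acorns_nuts": 47.4, "insects": 0.4, "mammals": 1.0, "salmon": 16.7,
         "other": 0.0},
}

#: Published per-year August pine-nut and September salmon EDC shares;
#: low years filled so the seven-year means sit near the published means.
_PINE_AUGUST = {2012: 19.7, 2013: 47.4, 2014: 47.5, 2015: 19.7, 2016: 47.3,
                2017: 19.7, 2018: 42.9}
_SALMON_SEPTEMBER = {2012: 30.0, 2013: 54.4, 2014: 30.0, 2015: 30.0,
                     2016: 65.4, 2017: 30.0, 2018: 72.2}

#: Scats per month-year: point-frame years match the published monthly n
#: divided over six years; 2012 (visual) the remainder of the monthly totals.
_SCATS_POINTFRAME = {6: 40, 7: 51, 8: 79, 9: 78, 10: 45}
_SCATS_VISUAL_2012 = {6: 25, 7: 95, 8: 76, 9: 41, 10: 78}

#: Seasonal log TH:HTL trajectories (session grid = SESSIONS). High-
#: consumption years dip little with an early minimum (mid-July); other
#: years keep declining to late August before recovering.
_CURVE_HIGH = (-0.375, -0.392, -0.390, -0.388, -0.383, -0.375, -0.365, -0.345)
_CURVE_LOW = (-0.370, -0.388, -0.402, -0.412, -0.405, -0.393, -0.378, -0.355)

_BEAR_IDS = ("BE", "DC", "DR", "GI", "HC", "KB", "KR", "LI", "RI", "WD", "WK", "WM")


@dataclass
class StudyConfig:
    """Generator parameters; the defaults are the study's conditions."""

    years: tuple = (2012, 2013, 2014, 2015, 2016, 2017, 2018)
    visual_years: tuple = (2012,)
    months: tuple = (6, 7, 8, 9, 10)
    items: pd.DataFrame = field(default_factory=_default_items)
    month_profiles: dict = field(default_factory=lambda: {
        m: dict(p) for m, p in _MONTH_PROFILES.items()})
    pine_august: dict = field(default_factory=lambda: dict(_PINE_AUGUST))
    salmon_september: dict = field(default_factory=lambda: dict(_SALMON_SEPTEMBER))
    dirichlet_concentration: float = 6.0
    scats_per_month: dict | None = None  # (year, month) -> n; None = defaults
    points_range: tuple = (200, 320)
    salmon_points_range: tuple = (60, 200)
    debris_beta: tuple = (2.0, 64.0)  # fecal-side nonfood share ~ Beta(a, b)
    vfv_noise_sd: float = 0.25  # lognormal sd of visual item estimates

    bears: tuple = _BEAR_IDS
    sessions: tuple = SESSIONS
    curve_high: tuple = _CURVE_HIGH
    curve_low: tuple = _CURVE_LOW
    rst_offset: float = -0.025
    sd_year: float = 0.012
    sd_bear: float = 0.015
    photo_gamma_shape: float = 600.0
    photos_per_session_mean: float = 3.6
    presence_prob: float = 0.85
    p_with_young: float = 0.40
    loss_hazard: float = 0.04
    unusable_photo_rate: float = 0.15
    rep_jitter_sd: float = 1.5
    ground_angle_range: tuple = (-8.0, 8.0)

    def n_scats(self, year: int, month: int) -> int:
        if self.scats_per_month is not None:
            return int(self.scats_per_month.get((year, month), 0))
        if year in self.visual_years:
            return _SCATS_VISUAL_2012.get(month, 0)
        return _SCATS_POINTFRAME.get(month, 0)

    def taxonomy(self) -> FoodItemTable:
        return FoodItemTable.from_frame(self.items)


def _year_month_profile(config: StudyConfig, year: int, month: int) -> dict:
    """Month profile with the year's pine (August) / salmon (September)
    share substituted; the remaining categories rescale to fill 100."""
    base = dict(config.month_profiles[month])
    total = sum(base.values())
    base = {c: 100.0 * v / total for c, v in base.items()}
    if month == 8 and year in config.pine_august:
        base = _substitute(base, "pine_nuts", config.pine_august[year])
    if month == 9 and year in config.salmon_september:
        base = _substitute(base, "salmon", config.salmon_september[year])
    return base


def _substitute(profile: dict, category: str, share: float) -> dict:
    rest = {c: v for c, v in profile.items() if c != category}
    rest_total = sum(rest.values())
    scale = (100.0 - share) / rest_total if rest_total > 0 else 0.0
    out = {c: v * scale for c, v in rest.items()}
    out[category] = share
    return out


def _item_profile(config: StudyConfig, category_profile: dict) -> tuple:
    """Expand a category profile to item level by fixed within-category
    weights; returns (item ids, shares summing to 1)."""
    items = config.items
    food = items[items["category"] != "nonfood"]
    ids, shares = [], []
    for row in food.itertuples():
        cat_share = category_profile.get(row.category, 0.0)
        ids.append(row.item_id)
        shares.append(cat_share * row.weight / 100.0)
    shares = np.asarray(shares)
    total = shares.sum()
    if total <= 0:
        raise ValueError("empty category profile")
    return ids, shares / total


def gen_diet(config: StudyConfig, seed) -> tuple:
    """Generate scat records (and parallel data for calibration).

    Returns ``(truth, records, calibration_pairs)`` where ``truth`` maps
    (year, month) to the true mean category diet (percent, EDC scale),
    ``records`` is a list of :class:`ScatRecord`, and
    ``calibration_pairs`` is a tidy frame of per-period (vFV, EDC)
    category pairs from the generator's parallel visual estimates.
    """
    rng = np.random.default_rng(seed)
    items = config.items
    cf_d = dict(zip(items["item_id"], items["cf_d"]))
    truth: dict = {}
    records: list = []
    cal_rows: list = []

    for year in config.years:
        visual = year in config.visual_years
        for month in config.months:
            n = config.n_scats(year, month)
            if n == 0:
                continue
            cat_profile = _year_month_profile(config, year, month)
            truth[(year, month)] = dict(cat_profile)
            ids, shares = _item_profile(config, cat_profile)
            positive = shares > 0
            period_fecal = np.zeros(len(ids))
            for j in range(n):
                alpha = config.dirichlet_concentration * shares[positive]
                comp = np.zeros(len(ids))
                comp[positive] = rng.dirichlet(alpha)
                # inverse-CF distortion: divide by CF_D, renormalize
                fecal = comp / np.array([cf_d[i] for i in ids])
                fecal /= fecal.sum()
                debris = rng.beta(*config.debris_beta)
                fecal_full = dict(zip(ids, fecal * (1.0 - debris)))
                fecal_full["debris"] = debris
                period_fecal += fecal * (1.0 - debris)
                scat_id = f"{year}-{month:02d}-{j:04d}"
                half = rng.choice(["early", "late", "unknown"], p=[0.475, 0.475, 0.05])
                salmon_share = fecal_full.get("salmon", 0.0)
                wet = float(np.exp(rng.normal(np.log(150.0), 0.5)))
                if visual:
                    vfv = _visual_estimate(fecal_full, rng, config.vfv_noise_sd)
                    records.append(ScatRecord(
                        scat_id=scat_id, year=year, month=month, half=half,
                        method="visual", vfv=vfv, wet_weight_g=wet))
                else:
                    lo, hi = (config.salmon_points_range if salmon_share > 0.3
                              else config.points_range)
                    n_points = int(rng.integers(lo, hi + 1))
                    counts = rng.multinomial(
                        n_points, np.array(list(fecal_full.values())))
                    pc = {k: int(c) for k, c in zip(fecal_full, counts) if c > 0}
                    if not pc:
                        pc = {max(fecal_full, key=fecal_full.get): n_points}
                    records.append(ScatRecord(
                        scat_id=scat_id, year=year, month=month, half=half,
                        method="point_frame", point_counts=pc, wet_weight_g=wet))
            if not visual and n > 0:
                # parallel visual estimates of the period mean, for the
                # vFV -> EDC calibration
                period_fecal /= period_fecal.sum()
                vfv_cat: dict = {}
                for i, item in enumerate(ids):
                    cat = items.loc[items["item_id"] == item, "category"].iloc[0]
                    noisy = period_fecal[i] * np.exp(rng.normal(0, config.vfv_noise_sd))
                    vfv_cat[cat] = vfv_cat.get(cat, 0.0) + 100.0 * noisy
                scale = 100.0 / sum(vfv_cat.values())
                for cat in CATEGORIES:
                    cal_rows.append({
                        "year": year, "month": month, "category": cat,
                        "vfv": vfv_cat.get(cat, 0.0) * scale,
                        "edc": cat_profile.get(cat, 0.0),
                    })
    pairs = pd.DataFrame(cal_rows, columns=["year", "month", "category", "vfv", "edc"])
    return truth, records, pairs


def _visual_estimate(fecal: dict, rng, noise_sd: float) -> dict:
    noisy = {k: v * np.exp(rng.normal(0.0, noise_sd)) for k, v in fecal.items() if v > 0}
    total = sum(noisy.values())
    vals = {k: round(100.0 * v / total, 1) for k, v in noisy.items()}
    # fix rounding drift so the record's 100 +/- 0.5 invariant holds
    drift = 100.0 - sum(vals.values())
    top = max(vals, key=vals.get)
    vals[top] = round(vals[top] + drift, 1)
    return vals


# ---------------------------------------------------------------------------
# Body-condition stream


def _baseline(config: StudyConfig, session: float, high_year: bool) -> float:
    grid = np.asarray(config.sessions, dtype=float)
    curve = np.asarray(config.curve_high if high_year else config.curve_low)
    return float(np.interp(session, grid, curve))


def _make_landmarks(ratio: float, rng, config: StudyConfig) -> tuple:
    """Three replicate landmark sets yielding ``ratio``, rotated by a
    random ground angle (returned alongside)."""
    htl = float(rng.uniform(450.0, 750.0))
    th = ratio * htl
    base = {
        "abdomen_lowest": (320.0, 240.0),
        "waist_highest": (340.0, 240.0 + th),
        "tail_base": (150.0, 400.0),
        "shoulder_highest": (150.0 + htl, 415.0),
    }
    angle = float(rng.uniform(*config.ground_angle_range))
    theta = np.radians(angle)
    c, s = np.cos(theta), np.sin(theta)
    reps = []
    for _ in range(3):
        rep = {}
        for name, (x, y) in base.items():
            if config.rep_jitter_sd > 0:
                x = x + rng.normal(0.0, config.rep_jitter_sd)
                y = y + rng.normal(0.0, config.rep_jitter_sd)
            rep[name] = (c * x - s * y, s * x + c * y)
        reps.append(rep)
    return tuple(reps), angle


def gen_condition(config: StudyConfig, seed, high_years=None) -> tuple:
    """Generate photographs and reproductive events.

    ``high_years`` is the set of years following the shallow (high
    consumption) trajectory; by default, the years whose configured
    August pine and September salmon shares are both high.

    Returns ``(photos, events, truth)`` with ``photos`` a list of
    :class:`~ursadiet.condition.PhotoRecord`, ``events`` a list of
    :class:`~ursadiet.condition.ReproductiveEvent`, and ``truth`` the
    generating curves, offsets, and random intercepts.
    """
    from .condition import PhotoRecord, ReproductiveEvent, DEFAULT_ATTRIBUTES

    rng = np.random.default_rng(seed)
    if high_years is None:
        pine_mean = np.mean(list(config.pine_august.values()))
        salmon_mean = np.mean(list(config.salmon_september.values()))
        high_years = {
            y for y in config.years
            if config.pine_august.get(y, 0) > pine_mean
            and config.salmon_september.get(y, 0) > salmon_mean
        }
    u_year = {y: float(rng.normal(0.0, config.sd_year)) for y in config.years}
    u_bear = {b: float(rng.normal(0.0, config.sd_bear)) for b in config.bears}

    photos: list = []
    events: list = []
    counter = 0
    for year in config.years:
        for bear in config.bears:
            if rng.uniform() < config.p_with_young:
                status = "with_cubs" if rng.uniform() < 0.5 else "with_yearlings"
            else:
                status = "solitary"
            loss_session = None
            if status != "solitary":
                for sess in config.sessions:
                    if rng.uniform() < config.loss_hazard:
                        loss_session = float(sess)
                        break
            events.append(ReproductiveEvent(
                bear_id=bear, year=year, status=status, loss_session=loss_session))
            offset = config.rst_offset if status != "solitary" else 0.0
            for sess in config.sessions:
                if rng.uniform() > config.presence_prob:
                    continue
                eta = (_baseline(config, sess, year in high_years)
                       + offset + u_year[year] + u_bear[bear])
                mean_ratio = float(np.exp(eta))
                n_photos = int(rng.poisson(config.photos_per_session_mean))
                for _ in range(n_photos):
                    ratio = float(rng.gamma(
                        config.photo_gamma_shape,
                        mean_ratio / config.photo_gamma_shape))
                    reps, angle = _make_landmarks(ratio, rng, config)
                    scores = {a: int(rng.integers(1, 3)) for a in DEFAULT_ATTRIBUTES}
                    if rng.uniform() < config.unusable_photo_rate:
                        bad = rng.choice(list(DEFAULT_ATTRIBUTES))
                        scores[bad] = 3
                    counter += 1
                    photos.append(PhotoRecord(
                        photo_id=f"P{counter:05d}", bear_id=bear, year=year,
                        session=float(sess), attribute_scores=scores,
                        ground_angle_deg=angle, landmarks=reps))
    truth = {
        "high_years": sorted(high_years),
        "curve_high": list(config.curve_high),
        "curve_low": list(config.curve_low),
        "sessions": [float(s) for s in config.sessions],
        "rst_offset": config.rst_offset,
        "u_year": {str(y): v for y, v in u_year.items()},
        "u_bear": u_bear,
    }
    return photos, events, truth


# ---------------------------------------------------------------------------
# Full-bundle writer


def gen_study(config: StudyConfig, seed, out_dir) -> dict:
    """Write a complete synthetic study to ``out_dir``: scats.csv,
    taxonomy.csv, photos.csv, repro.csv, calibration_pairs.csv, and
    truth.json. Deterministic: identical (config, seed) give
    byte-identical files. One RNG substream per component."""
    from pathlib import Path
    from . import io as uio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    diet_seed, cond_seed = ss.spawn(2)

    truth_diet, records, pairs = gen_diet(config, diet_seed)
    photos, events, truth_cond = gen_condition(config, cond_seed)

    uio.write_scats(records, out / "scats.csv")
    config.items.drop(columns="weight").to_csv(out / "taxonomy.csv", index=False)
    uio.write_photos(photos, out / "photos.csv")
    uio.write_repro(events, out / "repro.csv")
    pairs.to_csv(out / "calibration_pairs.csv", index=False, float_format="%.6f")
    truth = {
        "seed": int(seed),
        "diet": {f"{y}-{m:02d}": prof for (y, m), prof in truth_diet.items()},
        "condition": truth_cond,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {"scats": len(records), "photos": len(photos), "out": str(out)}
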