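"""CSV schemas, validated reading, and the end-to-end pipeline.

All interchange is plain CSV (UTF-8, "." decimal separator, empty
fields for missing values). Pipeline outputs carry a header comment
line with the configuration hash and seed so any table can be traced to
the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import condition as cond
from . import diet
from .calibration import ThroughOriginCalibrator, apply_calibration
from .gamm import (ModelSpec, build_design, candidate_models, fit_gamm,
                   predict_curve, rank_models, smooth_summary)

logger = logging.getLogger(__name__)

_SCAT_META = ["scat_id", "year", "month", "half", "method", "wet_weight_g"]
_LANDMARK_SHORT = {
    "abdomen": "abdomen_lowest", "waist": "waist_highest",
    "tail": "tail_base", "shoulder": "shoulder_highest",
}


class SchemaError(ValueError):
    pass


@dataclass
class ValidationReport:
    """Row-level rejections: (row number, reason) per rejected row."""

    rejected: list = field(default_factory=list)

    def reject(self, row: int, reason: str):
        self.rejected.append((row, reason))
        logger.warning("row %d rejected: %s", row, reason)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rejected, columns=["row", "reason"])


def _require(frame: pd.DataFrame, columns, what: str):
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _half_of(row) -> str:
    if "half" in row.index and isinstance(row["half"], str) and row["half"]:
        return row["half"]
    if "day" in row.index and pd.notna(row["day"]):
        return "early" if int(row["day"]) <= 15 else "late"
    return "unknown"


# ---------------------------------------------------------------------------
# scats


def read_scats(path) -> tuple:
    """Read scat records (wide or long format).

    Wide: scat_id, year, month, half|day, method, wet_weight_g, then one
    column per item. Long: the same meta columns plus item_id, value.
    Returns (records, ValidationReport).
    """
    frame = pd.read_csv(path, comment="#")
    report = ValidationReport()
    long_format = "item_id" in frame.columns
    _require(frame, ["scat_id", "year", "month", "method"], "scats")
    if long_format:
        _require(frame, ["value"], "scats (long)")
        groups = frame.groupby("scat_id", sort=False)
        rows = []
        for scat_id, g in groups:
            meta = g.iloc[0]
            values = dict(zip(g["item_id"], g["value"]))
            rows.append((g.index[0], meta, values))
    else:
        item_cols = [c for c in frame.columns if c not in _SCAT_META + ["day"]]
        rows = [
            (i, row, {c: row[c] for c in item_cols if pd.notna(row[c]) and row[c] != 0})
            for i, row in frame.iterrows()
        ]

    records = []
    for rownum, meta, values in rows:
        try:
            method = str(meta["method"])
            if any(v < 0 for v in values.values()):
                bad = [k for k, v in values.items() if v < 0]
                raise ValueError(f"negative value for item(s) {bad}")
            kwargs = dict(
                scat_id=str(meta["scat_id"]), year=int(meta["year"]),
                month=int(meta["month"]), half=_half_of(meta), method=method,
                wet_weight_g=float(meta.get("wet_weight_g", float("nan"))),
            )
            if method == "point_frame":
                record = diet.ScatRecord(point_counts={k: int(v) for k, v in values.items()},
                                         **kwargs)
            else:
                record = diet.ScatRecord(vfv={k: float(v) for k, v in values.items()},
                                         **kwargs)
            records.append(record)
        except (ValueError, KeyError) as exc:
            report.reject(int(rownum), str(exc))
    return records, report


def write_scats(records, path):
    items = sorted({k for r in records for k in (r.point_counts or r.vfv)})
    rows = []
    for r in records:
        row = {"scat_id": r.scat_id, "year": r.year, "month": r.month,
               "half": r.half, "method": r.method,
               "wet_weight_g": round(r.wet_weight_g, 1)}
        row.update(r.point_counts or r.vfv)
        rows.append(row)
    pd.DataFrame(rows, columns=_SCAT_META + items).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# photos / repro


def read_photos(path) -> tuple:
    """Read photo records: photo_id, bear_id, year, session (or
    month+day), ground_angle_deg, attr_* score columns, and
    rep{1..3}_{abdomen,waist,tail,shoulder}_{x,y} landmark columns."""
    frame = pd.read_csv(path, comment="#")
    _require(frame, ["photo_id", "bear_id", "year", "ground_angle_deg"], "photos")
    attr_cols = [c for c in frame.columns if c.startswith("attr_")]
    if not attr_cols:
        raise SchemaError("photos: no attr_* grading columns")
    report = ValidationReport()
    records = []
    for i, row in frame.iterrows():
        try:
            if "session" in frame.columns and pd.notna(row["session"]):
                session = float(row["session"])
            else:
                session = cond.session_of(int(row["month"]), int(row.get("day", 0)) or None)
            reps = []
            for r in (1, 2, 3):
                rep = {}
                for short, name in _LANDMARK_SHORT.items():
                    rep[name] = (float(row[f"rep{r}_{short}_x"]),
                                 float(row[f"rep{r}_{short}_y"]))
                reps.append(rep)
            records.append(cond.PhotoRecord(
                photo_id=str(row["photo_id"]), bear_id=str(row["bear_id"]),
                year=int(row["year"]), session=session,
                attribute_scores={c[len("attr_"):]: int(row[c]) for c in attr_cols},
                ground_angle_deg=float(row["ground_angle_deg"]),
                landmarks=tuple(reps),
            ))
        except (ValueError, KeyError) as exc:
            report.reject(int(i), str(exc))
    return records, report


def write_photos(photos, path):
    rows = []
    for p in photos:
        row = {"photo_id": p.photo_id, "bear_id": p.bear_id, "year": p.year,
               "session": p.session, "ground_angle_deg": round(p.ground_angle_deg, 4)}
        for attr, score in p.attribute_scores.items():
            row[f"attr_{attr}"] = score
        for r, rep in enumerate(p.landmarks, start=1):
            for short, name in _LANDMARK_SHORT.items():
                row[f"rep{r}_{short}_x"] = round(rep[name][0], 3)
                row[f"rep{r}_{short}_y"] = round(rep[name][1], 3)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_repro(path) -> list:
    frame = pd.read_csv(path, comment="#")
    _require(frame, ["bear_id", "year", "status"], "repro")
    events = []
    for _, row in frame.iterrows():
        loss = row.get("loss_session")
        events.append(cond.ReproductiveEvent(
            bear_id=str(row["bear_id"]), year=int(row["year"]),
            status=str(row["status"]),
            loss_session=float(loss) if pd.notna(loss) else None,
        ))
    return events


def write_repro(events, path):
    pd.DataFrame([
        {"bear_id": e.bear_id, "year": e.year, "status": e.status,
         "loss_session": e.loss_session}
        for e in events
    ]).to_csv(path, index=False)


def read_taxonomy(path) -> diet.FoodItemTable:
    return diet.FoodItemTable.from_frame(pd.read_csv(path, comment="#"))


def load_models(path) -> list:
    """Load a declarative candidate-model list (YAML: a list of mappings
    with keys name, smooth_by, fixed)."""
    import yaml

    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [
        ModelSpec(name=e["name"], smooth_by=e.get("smooth_by"),
                  fixed=tuple(e.get("fixed", ())))
        for e in entries
    ]


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Paths and analysis options for the end-to-end run."""

    scats: str
    taxonomy: str
    photos: str
    repro: str
    out_dir: str
    calibration_pairs: str | None = None
    basis: str = "edc"
    grouping: str = "month"
    calibrate: bool = True
    k: int = 5
    models: list | None = None  # None = full candidate set
    seed: int = 0

    def hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k != "models"}
        payload["models"] = [m.name for m in self.models] if self.models else "default"
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_output(frame: pd.DataFrame, path: Path, config: PipelineConfig):
    with open(path, "w") as fh:
        fh.write(f"# ursadiet config={config.hash()} seed={config.seed}\n")
        frame.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Outputs (all CSV, in ``config.out_dir``): diet_summary, annual_edc,
    year_classes, observations, selection, estimates, curves. On a stage
    failure, partial outputs are removed and a :class:`StageError`
    naming the stage is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list = []

    def emit(frame, name):
        path = out / f"{name}.csv"
        _write_output(frame, path, config)
        written.append(path)

    stage = "read"
    try:
        taxonomy = read_taxonomy(config.taxonomy)
        records, scat_report = read_scats(config.scats)
        photos, photo_report = read_photos(config.photos)
        events = read_repro(config.repro)
        logger.info("read %d scats (%d rejected), %d photos (%d rejected)",
                    len(records), len(scat_report.rejected),
                    len(photos), len(photo_report.rejected))

        stage = "diet"
        pf_records, pf_edc, pf_edec = [], [], []
        n_rejected = 0
        for r in records:
            if r.method != "point_frame":
                continue
            if not diet.accept_scat(r, taxonomy).accepted:
                n_rejected += 1
                continue
            prof = diet.apply_nonfood_rules(diet.compute_occupancy(r.point_counts),
                                            taxonomy)
            pf_records.append(r)
            pf_edc.append(diet.aggregate_categories(diet.compute_edc(prof, taxonomy),
                                                    taxonomy))
            pf_edec.append(diet.aggregate_categories(diet.compute_edec(prof, taxonomy),
                                                     taxonomy))
        logger.info("diet: %d point-frame scats accepted, %d rejected",
                    len(pf_records), n_rejected)
        summary_edc = diet.summarize_period(pf_records, pf_edc, config.grouping)
        summary_edec = diet.summarize_period(pf_records, pf_edec, config.grouping)
        summary_edc["basis"] = "edc"
        summary_edec["basis"] = "edec"
        emit(pd.concat([summary_edc, summary_edec], ignore_index=True), "diet_summary")

        stage = "annual"
        annual = diet.summarize_period(pf_records, pf_edc, "year_month")
        annual["basis"] = "edc"
        visual = [r for r in records if r.method == "visual"]
        if visual:
            if config.calibrate and config.calibration_pairs:
                pairs = pd.read_csv(config.calibration_pairs, comment="#")
                wide_v = pairs.pivot_table(index=["year", "month"], columns="category",
                                           values="vfv", fill_value=0.0)
                wide_e = pairs.pivot_table(index=["year", "month"], columns="category",
                                           values="edc", fill_value=0.0)
                calibrator = ThroughOriginCalibrator().fit(wide_v, wide_e)
                v_profiles = []
                for r in visual:
                    prof = diet.apply_nonfood_rules(
                        diet.DietProfile(basis="vfv", level="item", values=r.vfv),
                        taxonomy)
                    cat = diet.aggregate_categories(prof, taxonomy)
                    food = {k: v for k, v in cat.values.items() if k != diet.NONFOOD}
                    total = sum(food.values())
                    cat = diet.DietProfile(basis="vfv", level="category",
                                           values={k: 100 * v / total
                                                   for k, v in food.items()})
                    v_profiles.append(apply_calibration(cat, calibrator.model_))
                v_annual = diet.summarize_period(visual, v_profiles, "year_month")
                v_annual["basis"] = "edc_calibrated"
                annual = pd.concat([annual, v_annual], ignore_index=True)
            else:
                logger.warning(
                    "calibration off or no pairs: %d visual scats excluded from "
                    "EDC outputs", len(visual))
        emit(annual, "annual_edc")

        stage = "classification"
        aug = annual[(annual["key"] == "pine_nuts")
                     & annual["group"].str.endswith("/8")]
        sep = annual[(annual["key"] == "salmon")
                     & annual["group"].str.endswith("/9")]
        pine = {int(g.split("/")[0]): v for g, v in zip(aug["group"], aug["mean"])}
        salmon = {int(g.split("/")[0]): v for g, v in zip(sep["group"], sep["mean"])}
        years = sorted(set(pine) & set(salmon))
        classification = diet.classify_years({y: pine[y] for y in years},
                                             {y: salmon[y] for y in years})
        emit(pd.DataFrame([
            {"year": y, "pine_high": c.pine_high, "salmon_high": c.salmon_high,
             "diet1": c.diet1, "diet2": c.diet2}
            for y, c in sorted(classification.years.items())
        ]), "year_classes")

        stage = "condition"
        by_cell: dict = {}
        for p in photos:
            by_cell.setdefault((p.bear_id, p.year, p.session), []).append(p)
        conditions = [c for c in (cond.session_condition(v) for v in by_cell.values())
                      if c is not None]
        conditions = [c for c in conditions if c.year in classification.years]
        observations = cond.build_observations(conditions, events, classification)
        emit(observations, "observations")

        stage = "model"
        specs = config.models if config.models is not None else candidate_models()
        fits = []
        for spec in specs:
            bundle = build_design(spec, observations, k=config.k)
            fits.append(fit_gamm(bundle))
        selection = rank_models(fits)
        emit(selection, "selection")

        best = max(fits, key=lambda f: -f.aicc)
        est = best.fixed_table()
        est["kind"] = "parametric"
        sm = smooth_summary(best)
        sm = sm.rename(columns={"F": "t"})  # shared column layout
        sm["kind"] = "smooth"
        estimates = pd.concat([est, sm], ignore_index=True)
        emit(estimates, "estimates")

        stage = "curves"
        groups = _curve_groups(best.spec)
        sessions = np.linspace(min(cond.SESSIONS), max(cond.SESSIONS), 51)
        emit(predict_curve(best, sessions, groups), "curves")
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc

    return {
        "outputs": [str(p) for p in written],
        "n_scats": len(records),
        "n_photos": len(photos),
        "n_observations": int(len(observations)),
        "top_model": selection["model"].iloc[0],
    }


def _curve_groups(spec: ModelSpec) -> dict:
    if spec.smooth_by == "status":
        return {
            "solitary": {"status": "solitary", "diet1": True, "diet2": False},
            "with_young": {"status": "with_young", "diet1": True, "diet2": False},
        }
    if spec.smooth_by == "diet2":
        return {
            "low consumption": {"status": "solitary", "diet1": False, "diet2": True},
            "not low": {"status": "solitary", "diet1": True, "diet2": False},
        }
    # default/diet1 grouping: high vs low consumption years
    return {
        "high consumption": {"status": "solitary", "diet1": True, "diet2": False},
        "low consumption": {"status": "solitary", "diet1": False, "diet2": False},
    }
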