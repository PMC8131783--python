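"""Photograph-based body condition (TH:HTL).

A lateral photograph of a bear is graded for quality and posture, its
landmark coordinates are rotated so the ground line is horizontal, and
two lengths are read off: torso height TH (vertical distance from the
lowest point of the abdomen to the highest point of the waist) and
horizontal torso length HTL (horizontal distance from the base of the
tail to the highest part of the shoulder). The ratio TH:HTL, a
dimensionless condition index, is computed from the means of three
replicate measurements per photograph and summarized as the median over
photographs within a bear x year x session cell.

Inclusion rules: photographs with any attribute scored 3 (poor) are
removed; a session value needs >= 2 usable photographs; a bear-year
needs >= 2 session values; sessions from the loss of dependent offspring
onward are excluded for the affected female.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median

import numpy as np
import pandas as pd

#: Within-year session coding: June, July, early/late August, early/late
#: September, October, November.
SESSIONS = (1.0, 2.0, 3.0, 3.5, 4.0, 4.5, 5.0, 6.0)

#: Default photo-grading attributes (any score of 3 removes the photo).
DEFAULT_ATTRIBUTES = (
    "focus",
    "lateral_orientation",
    "posture",
    "obstruction",
    "ground_visibility",
)

LANDMARK_NAMES = ("abdomen_lowest", "waist_highest", "tail_base", "shoulder_highest")


class DegenerateLandmarkError(ValueError):
    """A replicate measurement with zero TH or HTL."""


def session_of(month: int, day: int | None = None) -> float:
    """Map a calendar date to the session code.

    August and September split semimonthly (day <= 15 = early); June,
    July, October, and November are whole-month sessions.
    """
    if month == 6:
        return 1.0
    if month == 7:
        return 2.0
    if month == 8:
        if day is None:
            raise ValueError("August needs a day for the semimonthly split")
        return 3.0 if day <= 15 else 3.5
    if month == 9:
        if day is None:
            raise ValueError("September needs a day for the semimonthly split")
        return 4.0 if day <= 15 else 4.5
    if month == 10:
        return 5.0
    if month == 11:
        return 6.0
    raise ValueError(f"month {month} outside the June-November study window")


@dataclass(frozen=True)
class PhotoRecord:
    photo_id: str
    bear_id: str
    year: int
    session: float
    attribute_scores: dict
    ground_angle_deg: float
    landmarks: tuple  # 3 replicate dicts: name -> (x, y)

    def __post_init__(self):
        for attr, score in self.attribute_scores.items():
            if score not in (1, 2, 3):
                raise ValueError(f"attribute {attr!r} scored {score}; must be 1, 2 or 3")


@dataclass(frozen=True)
class MorphMeasure:
    th_px: tuple
    htl_px: tuple

    @property
    def th_htl(self) -> float:
        return (sum(self.th_px) / len(self.th_px)) / (sum(self.htl_px) / len(self.htl_px))


@dataclass(frozen=True)
class SessionCondition:
    bear_id: str
    year: int
    session: float
    th_htl: float
    n_photos: int


@dataclass(frozen=True)
class ReproductiveEvent:
    """A female's status for one year, with the first session after
    offspring loss or family break-up (if any)."""

    bear_id: str
    year: int
    status: str  # "solitary" | "with_cubs" | "with_yearlings"
    loss_session: float | None = None

    def __post_init__(self):
        if self.status not in ("solitary", "with_cubs", "with_yearlings"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.loss_session is not None and self.status == "solitary":
            raise ValueError("loss_session is only defined for females with offspring")

    @property
    def collapsed_status(self) -> str:
        """Cubs and yearlings collapse to one level: mothers with either
        have similar condition, so the model uses solitary vs with_young."""
        return "solitary" if self.status == "solitary" else "with_young"


def grade_photo(attribute_scores: dict) -> bool:
    """Usable iff no attribute scored 3 (poor quality)."""
    if not attribute_scores:
        raise ValueError("no attribute scores supplied")
    for attr, score in attribute_scores.items():
        if score not in (1, 2, 3):
            raise ValueError(f"attribute {attr!r} scored {score}; must be 1, 2 or 3")
    return all(score != 3 for score in attribute_scores.values())


def rectify_landmarks(landmarks: dict, ground_angle_deg: float) -> dict:
    """Rotate all points by -ground_angle_deg about the origin.

    ``ground_angle_deg`` is the counterclockwise tilt of the ground line
    in the photograph; the rotation brings the ground back to
    horizontal. Rotation is an isometry, so all pairwise distances are
    preserved.
    """
    theta = math.radians(-ground_angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    return {
        name: (c * x - s * y, s * x + c * y)
        for name, (x, y) in landmarks.items()
    }


def measure_th_htl(replicates) -> MorphMeasure:
    """TH:HTL from three rectified replicate landmark sets.

    Per replicate TH = |y(waist_highest) - y(abdomen_lowest)| and
    HTL = |x(shoulder_highest) - x(tail_base)|; the ratio is taken
    between the replicate means, not averaged per replicate.
    """
    th, htl = [], []
    for rep in replicates:
        t = abs(rep["waist_highest"][1] - rep["abdomen_lowest"][1])
        h = abs(rep["shoulder_highest"][0] - rep["tail_base"][0])
        if t == 0 or h == 0:
            raise DegenerateLandmarkError("replicate with zero TH or HTL")
        th.append(t)
        htl.append(h)
    return MorphMeasure(th_px=tuple(th), htl_px=tuple(htl))


def photo_th_htl(photo: PhotoRecord) -> float | None:
    """Grade, rectify, and measure one photograph; None if unusable."""
    if not grade_photo(photo.attribute_scores):
        return None
    rectified = [rectify_landmarks(rep, photo.ground_angle_deg) for rep in photo.landmarks]
    return measure_th_htl(rectified).th_htl


def session_condition(photos) -> SessionCondition | None:
    """Median TH:HTL over usable photos of one bear x year x session.

    Returns None with fewer than two usable photographs (an even count
    takes the mean of the two central values).
    """
    photos = list(photos)
    if not photos:
        return None
    keys = {(p.bear_id, p.year, p.session) for p in photos}
    if len(keys) != 1:
        raise ValueError("photos span more than one bear x year x session")
    ratios = [r for r in (photo_th_htl(p) for p in photos) if r is not None]
    if len(ratios) < 2:
        return None
    bear_id, year, session = next(iter(keys))
    return SessionCondition(
        bear_id=bear_id, year=year, session=session,
        th_htl=float(median(ratios)), n_photos=len(ratios),
    )


def build_observations(
    session_conditions,
    reproductive_events,
    year_classification=None,
    loss_rule: str = "inclusive",
) -> pd.DataFrame:
    """Assemble the modelling table, applying the exclusion rules.

    * females that lost offspring: sessions from ``loss_session`` onward
      are dropped (``loss_rule="inclusive"``, the default, drops the
      loss session itself; ``"exclusive"`` keeps it);
    * bear-years left with fewer than two sessions are dropped (the
      re-check runs after the loss truncation);
    * reproductive status is collapsed to solitary / with_young;
    * the year's diet1/diet2 labels are attached when a
      :class:`~ursadiet.diet.YearClassification` is given.
    """
    if loss_rule not in ("inclusive", "exclusive"):
        raise ValueError(f"unknown loss_rule {loss_rule!r}")
    events = {(e.bear_id, e.year): e for e in reproductive_events}
    rows = []
    for sc in session_conditions:
        key = (sc.bear_id, sc.year)
        if key not in events:
            raise ValueError(f"no reproductive record for bear-year {key}")
        ev = events[key]
        if ev.loss_session is not None:
            cut = ev.loss_session if loss_rule == "inclusive" else np.nextafter(
                ev.loss_session, np.inf)
            if sc.session >= cut:
                continue
        rows.append({
            "bear_id": sc.bear_id,
            "year": sc.year,
            "session": sc.session,
            "th_htl": sc.th_htl,
            "n_photos": sc.n_photos,
            "status": ev.collapsed_status,
        })
    frame = pd.DataFrame(
        rows, columns=["bear_id", "year", "session", "th_htl", "n_photos", "status"]
    )
    if not frame.empty:
        counts = frame.groupby(["bear_id", "year"])["session"].transform("size")
        frame = frame[counts >= 2].reset_index(drop=True)
    if year_classification is not None:
        frame["diet1"] = [
            year_classification.years[y].diet1 for y in frame["year"]
        ] if not frame.empty else pd.Series(dtype=bool)
        frame["diet2"] = [
            year_classification.years[y].diet2 for y in frame["year"]
        ] if not frame.empty else pd.Series(dtype=bool)
    return frame
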