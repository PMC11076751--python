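"""Surgical-planning accuracy metrics.

Seven quantities are computed for one participant's drawing set against the
projected tumor silhouette:

* painted area (mm²), covered tumor area and **percent tumor coverage**
  (covered / silhouette area × 100), and **excess coverage** (painted area
  falling outside the silhouette, mm²);
* **linear-incision deviation**: minimum distance (mm) from the tumor
  epicenter (silhouette area centroid) to the drawn incision;
* **craniotomy score** (0–4): one point per craniotomy edge whose signed
  margin to the tumor border lies in the closed 5–15 mm band;
* **U-incision score** (0–4): the three drawn limbs scored like craniotomy
  edges, plus one point if the imaginary line closing the flap base is
  within the band;
* **craniotomy margin-deviation sum** (mm): sum over the four edges of the
  absolute deviation of the margin from the 10 mm acceptable standard.

Burr holes are carried in the data model but not scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from . import projection as proj
from .errors import GeometryError, InvalidInputError, UndefinedMarginError
from .projection import Quad2D

__all__ = [
    "AnnotationSet",
    "CoverageResult",
    "AssessmentResult",
    "MARGIN_BAND_MM",
    "STANDARD_MARGIN_MM",
    "METRIC_COLUMNS",
    "coverage_metrics",
    "incision_deviation",
    "craniotomy_score",
    "u_incision_score",
    "margin_deviation_sum",
    "assess",
    "assess_cohort",
]

#: Closed acceptance band for a craniotomy edge margin, mm.
MARGIN_BAND_MM = (5.0, 15.0)
#: Center of the band: the "acceptable standard" margin, mm.
STANDARD_MARGIN_MM = 10.0

#: Metric columns (with units) as serialized to CSV, in reporting order.
METRIC_COLUMNS = (
    "percent_coverage_pct",
    "excess_mm2",
    "painted_area_mm2",
    "incision_deviation_mm",
    "u_score_points",
    "craniotomy_score_points",
    "margin_deviation_sum_mm",
)

_DEFAULT_LAYERS = {
    "painted": "skin",
    "linear_incision": "skin",
    "u_incision": "skin",
    "burr_holes": "bone",
    "craniotomy": "bone",
}


@dataclass
class AnnotationSet:
    """One participant's drawings for one assessment, in plane coordinates (mm).

    ``assessment`` is ``"AA1"`` (post-MRI planning) or ``"AA2"`` (post-3D-model
    planning). ``layers`` records the model layer each element was drawn on.
    """

    painted: object  # shapely Polygon/MultiPolygon
    linear_incision: LineString
    u_incision: LineString  # 4 vertices = 3 limbs, base open
    burr_holes: np.ndarray  # (n, 2)
    craniotomy: Quad2D
    assessment: str = "AA1"
    layers: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_LAYERS))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assessment not in ("AA1", "AA2"):
            raise InvalidInputError(f"assessment must be AA1 or AA2, got {self.assessment!r}")
        self.painted = proj.as_region(self.painted)
        if not isinstance(self.linear_incision, LineString):
            self.linear_incision = proj.make_polyline(self.linear_incision)
        if not isinstance(self.u_incision, LineString):
            self.u_incision = proj.make_polyline(self.u_incision)
        if len(self.u_incision.coords) != 4:
            raise InvalidInputError("u_incision must have exactly 4 vertices (3 limbs)")
        self.burr_holes = np.atleast_2d(np.asarray(self.burr_holes, dtype=float))
        if not isinstance(self.craniotomy, Quad2D):
            self.craniotomy = Quad2D(np.asarray(self.craniotomy, dtype=float))


@dataclass(frozen=True)
class CoverageResult:
    """Painted-region coverage of the tumor silhouette."""

    painted_area: float  # mm²
    covered_area: float  # mm²
    percent_coverage: float  # %
    excess: float  # mm²


@dataclass(frozen=True)
class AssessmentResult:
    """The seven metric values for one :class:`AnnotationSet`."""

    coverage: CoverageResult
    incision_deviation: float  # mm
    u_score: int  # 0-4
    cran_score: int  # 0-4
    margin_deviation_sum: float  # mm

    def as_row(self) -> dict:
        return {
            "percent_coverage_pct": self.coverage.percent_coverage,
            "excess_mm2": self.coverage.excess,
            "painted_area_mm2": self.coverage.painted_area,
            "incision_deviation_mm": self.incision_deviation,
            "u_score_points": self.u_score,
            "craniotomy_score_points": self.cran_score,
            "margin_deviation_sum_mm": self.margin_deviation_sum,
        }


def coverage_metrics(painted, silhouette) -> CoverageResult:
    """Coverage of the tumor silhouette by the painted region.

    percent coverage = 100 × overlap / silhouette area; excess = painted area
    outside the silhouette. The identity painted = covered + excess is exact.
    """
    p = proj.as_region(painted)
    s = proj.as_region(silhouette)
    s_area = s.area
    if s_area <= 0:
        raise GeometryError("silhouette area must be positive")
    painted_area = p.area
    covered = min(p.intersection(s).area, painted_area, s_area)
    return CoverageResult(
        painted_area=painted_area,
        covered_area=covered,
        percent_coverage=min(100.0 * covered / s_area, 100.0),
        excess=max(painted_area - covered, 0.0),
    )


def incision_deviation(incision, silhouette) -> float:
    """Minimum distance (mm) from the tumor epicenter to the drawn incision."""
    c = proj.centroid(silhouette)
    return proj.min_distance(c, incision)


_BAND_TOL = 1e-9  # closed band: boundary ties are inclusive despite float noise


def _edge_score(edge, silhouette, convention: str, band) -> int:
    try:
        m = proj.edge_margin(edge, silhouette, convention)
    except UndefinedMarginError:
        warnings.warn("edge margin undefined; edge scored 0", stacklevel=3)
        return 0
    return int(band[0] - _BAND_TOL <= m <= band[1] + _BAND_TOL)


def craniotomy_score(
    quad: Quad2D, silhouette, convention: str = "midpoint-ray", band=MARGIN_BAND_MM
) -> int:
    """Composite craniotomy score: one point per edge inside the margin band."""
    if not isinstance(quad, Quad2D):
        quad = Quad2D(np.asarray(quad, dtype=float))
    return sum(_edge_score(e, silhouette, convention, band) for e in quad.edges())


def u_incision_score(
    u, silhouette, convention: str = "midpoint-ray", band=MARGIN_BAND_MM
) -> int:
    """U-shaped (horseshoe) incision score.

    The three drawn limbs are scored like craniotomy edges; the imaginary
    line connecting the two open corners (the flap base) contributes the
    fourth point if it lies within the band.
    """
    if not isinstance(u, LineString):
        u = proj.make_polyline(u)
    pts = np.asarray(u.coords)
    if pts.shape[0] != 4:
        raise InvalidInputError("U-incision must have exactly 4 vertices (3 limbs)")
    limbs = [pts[i : i + 2] for i in range(3)]
    base = np.array([pts[3], pts[0]])
    return sum(_edge_score(e, silhouette, convention, band) for e in (*limbs, base))


def margin_deviation_sum(
    quad: Quad2D,
    silhouette,
    standard_margin: float = STANDARD_MARGIN_MM,
    convention: str = "midpoint-ray",
) -> float:
    """Sum over the four edges of |margin − standard| (mm).

    A continuous alternative to the 0-4 craniotomy score; 0 iff every edge
    sits exactly at the acceptable standard margin. Edges whose margin is
    undefined are excluded with a warning.
    """
    if not isinstance(quad, Quad2D):
        quad = Quad2D(np.asarray(quad, dtype=float))
    total = 0.0
    for e in quad.edges():
        try:
            m = proj.edge_margin(e, silhouette, convention)
        except UndefinedMarginError:
            warnings.warn("edge margin undefined; edge excluded from deviation sum", stacklevel=2)
            continue
        total += abs(m - standard_margin)
    return total


def assess(
    annotation: AnnotationSet,
    silhouette,
    standard_margin: float = STANDARD_MARGIN_MM,
    convention: str = "midpoint-ray",
    band=MARGIN_BAND_MM,
) -> AssessmentResult:
    """All seven metrics for one annotation set.

    ``silhouette`` may be a planar region or a phantom model (anything with a
    ``silhouette()`` method).
    """
    if hasattr(silhouette, "silhouette"):
        silhouette = silhouette.silhouette()
    return AssessmentResult(
        coverage=coverage_metrics(annotation.painted, silhouette),
        incision_deviation=incision_deviation(annotation.linear_incision, silhouette),
        u_score=u_incision_score(annotation.u_incision, silhouette, convention, band),
        cran_score=craniotomy_score(annotation.craniotomy, silhouette, convention, band),
        margin_deviation_sum=margin_deviation_sum(
            annotation.craniotomy, silhouette, standard_margin, convention
        ),
    )


def assess_cohort(records: Iterable, silhouette, **kwargs) -> pd.DataFrame:
    """Metric table for a simulated cohort (one row per participant × assessment)."""
    if hasattr(silhouette, "silhouette"):
        silhouette = silhouette.silhouette()
    rows = []
    for rec in records:
        for ann in (rec.pre, rec.post):
            res = assess(ann, silhouette, **kwargs)
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "group": rec.group,
                    "assessment": ann.assessment,
                    **res.as_row(),
                }
            )
    return pd.DataFrame(rows)
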