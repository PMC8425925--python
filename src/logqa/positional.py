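"""Machine-parameter QA: delivered vs planned positions under TG-142-style
tolerances, with leaf-exclusion rules.

Per segment, the delivered beam-on mean gantry angle, diaphragm edges and
leaf positions are compared with the plan.  Leaf pairs are classified before
judging:

* ``under_diaphragm`` -- the pair's y-interval does not intersect the open
  diaphragm y-interval, so the pair is radiation-shielded;
* ``guard`` -- within ``guard_pairs`` pairs of the outermost pair that does
  intersect the opening (leaves tracking the field edge but dosimetrically
  irrelevant);
* ``closed_parked`` -- a closed pair (gap <= ``closed_gap_mm``) under the
  diaphragm: exactly the pairs an MLC controller may drive to its park
  positions regardless of the plan;
* ``in_field`` -- everything else.

Excluded statuses (all but ``in_field``) carry their raw deviation in the
report but never affect the pass verdict: a controller park override can
produce tens of millimetres of "deviation" on shielded closed leaves with no
dosimetric consequence, and must not fail an otherwise clean delivery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fluence import DeliveredSegment
from .rtplan import BeamPlan, MachineGeometry, PlanSegment
from .simulate import DEFAULT_CLOSED_GAP_MM

__all__ = [
    "ToleranceSet",
    "LeafStatus",
    "SegmentDeviation",
    "DeviationReport",
    "TOLERANCE_PROFILES",
    "classify_leaf",
    "positional_report",
    "wrap_angle_deg",
]

EXCLUDED_STATUSES = ("guard", "under_diaphragm", "closed_parked")


@dataclass(frozen=True)
class ToleranceSet:
    """Positional tolerances (TG-142-style machine QA defaults).

    ``collimator_deg`` is judged only when a tolerance is supplied; couch
    coordinates are recorded in logs but never judged.
    """

    gantry_deg: float = 1.0
    jaw_mm: float = 2.0
    mlc_mm: float = 1.0
    collimator_deg: float | None = None

    def __post_init__(self) -> None:
        if self.gantry_deg <= 0 or self.jaw_mm <= 0 or self.mlc_mm <= 0:
            raise ValueError("tolerances must be > 0")


#: "tg142" is the shipped default; "strict" tightens the gantry bound to
#: the agreement level observed on a well-commissioned clinical machine.
TOLERANCE_PROFILES: dict[str, ToleranceSet] = {
    "tg142": ToleranceSet(),
    "strict": ToleranceSet(gantry_deg=0.2, jaw_mm=2.0, mlc_mm=1.0),
}


@dataclass
class LeafStatus:
    pair_index: int
    bank: str  # "A" | "B"
    status: str
    raw_deviation_mm: float
    excluded: bool
    within_tolerance: bool | None  # defined only when not excluded


@dataclass
class SegmentDeviation:
    segment_index: int
    gantry_dev_deg: float
    jaw_devs_mm: tuple[float, float, float, float]  # x1, x2, y1, y2
    leaf_statuses: list[LeafStatus]


@dataclass
class DeviationReport:
    segments: list[SegmentDeviation]
    tolerances: ToleranceSet
    segment_count_mismatch: bool = False
    n_plan_segments: int = 0
    n_delivered_segments: int = 0
    max_gantry_dev_deg: float = 0.0
    max_jaw_dev_mm: float = 0.0
    max_mlc_dev_mm: float = 0.0  # over non-excluded leaves only
    max_excluded_mlc_dev_mm: float = 0.0
    failing_pairs: list[tuple[int, int, str]] = field(default_factory=list)
    gantry_pass: bool = True
    jaw_pass: bool = True
    mlc_pass: bool = True
    collimator_pass: bool | None = None

    @property
    def overall_pass(self) -> bool:
        passes = [self.gantry_pass, self.jaw_pass, self.mlc_pass,
                  not self.segment_count_mismatch]
        if self.collimator_pass is not None:
            passes.append(self.collimator_pass)
        return all(passes)

    def summary(self) -> dict:
        return {
            "overall_pass": self.overall_pass,
            "segment_count_mismatch": self.segment_count_mismatch,
            "n_plan_segments": self.n_plan_segments,
            "n_delivered_segments": self.n_delivered_segments,
            "max_gantry_dev_deg": self.max_gantry_dev_deg,
            "max_jaw_dev_mm": self.max_jaw_dev_mm,
            "max_mlc_dev_mm": self.max_mlc_dev_mm,
            "max_excluded_mlc_dev_mm": self.max_excluded_mlc_dev_mm,
            "gantry_pass": self.gantry_pass,
            "jaw_pass": self.jaw_pass,
            "mlc_pass": self.mlc_pass,
            "collimator_pass": self.collimator_pass,
            "failing_pairs": [list(t) for t in self.failing_pairs],
            "excluded_leaves": [
                {
                    "segment": s.segment_index,
                    "pair": ls.pair_index,
                    "bank": ls.bank,
                    "status": ls.status,
                    "raw_deviation_mm": ls.raw_deviation_mm,
                }
                for s in self.segments
                for ls in s.leaf_statuses
                if ls.excluded and abs(ls.raw_deviation_mm) > 0
            ],
        }


def wrap_angle_deg(delta: float) -> float:
    """Wrap an angle difference to (-180, 180]."""
    a = (delta + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def classify_leaf(
    pair_index: int,
    plan_a_mm: float,
    plan_b_mm: float,
    diaphragm_y1_mm: float,
    diaphragm_y2_mm: float,
    geometry: MachineGeometry,
    guard_pairs: int = 1,
    closed_gap_mm: float = DEFAULT_CLOSED_GAP_MM,
) -> str:
    """Classify one leaf pair from its *planned* state (total function).

    Classification is plan-side by construction: the exclusion rule must not
    depend on the delivered positions it is meant to excuse.
    """
    statuses = _classify_pairs(
        np.asarray([plan_a_mm]), np.asarray([plan_b_mm]),
        diaphragm_y1_mm, diaphragm_y2_mm, geometry, guard_pairs, closed_gap_mm,
        only_pair=pair_index,
    )
    return statuses[pair_index]


def _classify_pairs(
    plan_a: np.ndarray,
    plan_b: np.ndarray,
    y1: float,
    y2: float,
    geometry: MachineGeometry,
    guard_pairs: int,
    closed_gap_mm: float,
    only_pair: int | None = None,
) -> dict[int, str]:
    n = geometry.n_leaf_pairs
    inter = np.zeros(n, dtype=bool)
    for i in range(n):
        low, high = geometry.pair_y_interval(i)
        inter[i] = low < y2 and high > y1
    in_idx = np.nonzero(inter)[0]
    guard_set: set[int] = set()
    if in_idx.size:
        lo, hi = int(in_idx[0]), int(in_idx[-1])
        for gshift in range(1, guard_pairs + 1):
            guard_set.update({lo - gshift, hi + gshift})
        guard_set = {i for i in guard_set if 0 <= i < n}

    def status_of(i: int) -> str:
        if inter[i]:
            return "in_field"
        if i in guard_set:
            return "guard"
        # full arrays or single-pair call: gap from the matching entry
        idx = 0 if plan_a.size == 1 else i
        if plan_b[idx] - plan_a[idx] <= closed_gap_mm:
            return "closed_parked"
        return "under_diaphragm"

    pairs = range(n) if only_pair is None else [only_pair]
    return {i: status_of(i) for i in pairs}


def positional_report(
    plan: BeamPlan,
    segments: list[DeliveredSegment],
    tolerances: ToleranceSet | None = None,
    guard_pairs: int = 1,
    closed_gap_mm: float = DEFAULT_CLOSED_GAP_MM,
) -> DeviationReport:
    """Compare delivered segments against plan segments.

    A segment-count mismatch is itself a reported failure (the common prefix
    is still compared so the report stays informative).  Deviations are
    delivered-mean minus plan value; the gantry deviation is wrapped to
    (-180, 180], so it is invariant to either angle gaining a full turn.
    """
    if not segments:
        raise ValueError("empty delivered-segment list")
    tol = tolerances or ToleranceSet()
    g = plan.geometry
    report = DeviationReport(
        segments=[], tolerances=tol,
        segment_count_mismatch=len(segments) != len(plan.segments),
        n_plan_segments=len(plan.segments),
        n_delivered_segments=len(segments),
    )
    max_coll = 0.0
    for ps, ds in zip(plan.segments, segments):
        gantry_dev = wrap_angle_deg(ds.gantry_deg - ps.gantry_deg)
        jaw_devs = (
            ds.diaphragm_x1_mm - ps.diaphragm_x1_mm,
            ds.diaphragm_x2_mm - ps.diaphragm_x2_mm,
            ds.diaphragm_y1_mm - ps.diaphragm_y1_mm,
            ds.diaphragm_y2_mm - ps.diaphragm_y2_mm,
        )
        statuses = _classify_pairs(
            ps.leaf_a_mm, ps.leaf_b_mm,
            ps.diaphragm_y1_mm, ps.diaphragm_y2_mm,
            g, guard_pairs, closed_gap_mm,
        )
        leaf_statuses: list[LeafStatus] = []
        for i in range(g.n_leaf_pairs):
            status = statuses[i]
            excluded = status in EXCLUDED_STATUSES
            for bank, plan_pos, del_pos in (
                ("A", float(ps.leaf_a_mm[i]), float(ds.leaf_a_mm[i])),
                ("B", float(ps.leaf_b_mm[i]), float(ds.leaf_b_mm[i])),
            ):
                dev = del_pos - plan_pos
                within = None if excluded else abs(dev) <= tol.mlc_mm
                leaf_statuses.append(
                    LeafStatus(i, bank, status, dev, excluded, within)
                )
                if excluded:
                    report.max_excluded_mlc_dev_mm = max(
                        report.max_excluded_mlc_dev_mm, abs(dev))
                else:
                    report.max_mlc_dev_mm = max(report.max_mlc_dev_mm, abs(dev))
                    if not within:
                        report.failing_pairs.append((ps.index, i, bank))
        report.segments.append(
            SegmentDeviation(ps.index, gantry_dev, jaw_devs, leaf_statuses)
        )
        report.max_gantry_dev_deg = max(report.max_gantry_dev_deg, abs(gantry_dev))
        report.max_jaw_dev_mm = max(report.max_jaw_dev_mm, max(abs(d) for d in jaw_devs))
        max_coll = max(max_coll, abs(wrap_angle_deg(ds.collimator_deg - ps.collimator_deg)))

    report.gantry_pass = report.max_gantry_dev_deg <= tol.gantry_deg
    report.jaw_pass = report.max_jaw_dev_mm <= tol.jaw_mm
    report.mlc_pass = not report.failing_pairs
    if tol.collimator_deg is not None:
        report.collimator_pass = max_coll <= tol.collimator_deg
    return report
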