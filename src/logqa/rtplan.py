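"""Step-and-shoot treatment plan model and plan I/O.

A beam is modelled as an ordered list of static segments: for each segment the
MLC aperture, diaphragm (jaw) edges and gantry/collimator angles are held while
a fixed number of monitor units (MU) is delivered.  Two on-disk representations
are supported:

* DICOM RT Plan (standard IOD, static beams) via :mod:`pydicom`;
* a documented JSON "simple plan" schema used for fixtures and interchange.

Internal conventions: millimetres at isocenter, degrees, MU, IEC 61217 axes.
Leaf pairs are indexed 0-based from the most negative coordinate along the
leaf-width axis (here "Y"; leaves travel along "X").
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

__all__ = [
    "MachineGeometry",
    "PlanSegment",
    "BeamPlan",
    "PlanValidationError",
    "SchemaError",
    "read_rtplan",
    "write_rtplan",
    "read_simple_plan",
    "write_simple_plan",
    "default_geometry",
]

SIMPLE_PLAN_FORMAT = "logqa-plan v1"

RTPLAN_SOP_CLASS_UID = "1.2.840.10008.5.1.4.1.1.481.5"


class PlanValidationError(ValueError):
    """A plan object violates a structural invariant."""


class SchemaError(ValueError):
    """A simple-plan JSON document violates the documented schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MachineGeometry:
    """Static description of the MLC/jaw geometry at isocenter.

    ``park_positions_mm`` are the coordinates at which the MLC controller
    parks closed, jaw-shielded leaf pairs regardless of the planned position
    (bank A then bank B).  They must lie outside the field extent along the
    leaf travel axis, so a parked pair can never irradiate.
    """

    n_leaf_pairs: int = 80
    leaf_width_mm: float = 7.0
    leaf_travel_axis: str = "X"
    max_field_x_mm: float = 240.0
    max_field_y_mm: float = 560.0
    park_positions_mm: tuple[float, float] = (130.0, 134.0)

    def __post_init__(self) -> None:
        if self.n_leaf_pairs < 1:
            raise PlanValidationError("n_leaf_pairs must be >= 1")
        if self.leaf_width_mm <= 0:
            raise PlanValidationError("leaf_width_mm must be > 0")
        half = self.max_field_x_mm / 2.0
        if not all(abs(p) > half for p in self.park_positions_mm):
            raise PlanValidationError(
                "park positions must lie outside the max field extent "
                f"(|p| > {half} mm) along the travel axis"
            )

    @property
    def bank_span_mm(self) -> float:
        """Total extent of the leaf bank along the leaf-width axis."""
        return self.n_leaf_pairs * self.leaf_width_mm

    def pair_y_interval(self, pair_index: int) -> tuple[float, float]:
        """Half-open [low, high) y-interval covered by a leaf pair."""
        low = -self.bank_span_mm / 2.0 + pair_index * self.leaf_width_mm
        return low, low + self.leaf_width_mm

    def pair_index_at(self, y_mm: float) -> int:
        """Leaf pair owning coordinate ``y_mm`` (half-open rows); -1 if outside."""
        i = math.floor((y_mm + self.bank_span_mm / 2.0) / self.leaf_width_mm)
        return i if 0 <= i < self.n_leaf_pairs else -1


@dataclass
class PlanSegment:
    """One static aperture and its meterset.

    Leaf positions are bank coordinates on the travel axis at isocenter with
    the aperture of pair *i* being the closed interval
    ``[leaf_a_mm[i], leaf_b_mm[i]]`` (``a_i <= b_i``; equal means closed).
    """

    index: int
    mu: float
    gantry_deg: float
    collimator_deg: float
    leaf_a_mm: np.ndarray
    leaf_b_mm: np.ndarray
    diaphragm_x1_mm: float
    diaphragm_x2_mm: float
    diaphragm_y1_mm: float
    diaphragm_y2_mm: float

    def __post_init__(self) -> None:
        self.leaf_a_mm = np.asarray(self.leaf_a_mm, dtype=float)
        self.leaf_b_mm = np.asarray(self.leaf_b_mm, dtype=float)

    def validate(self, geometry: MachineGeometry) -> None:
        if self.mu < 0:
            raise PlanValidationError(f"segment {self.index}: mu must be >= 0")
        n = geometry.n_leaf_pairs
        if self.leaf_a_mm.shape != (n,) or self.leaf_b_mm.shape != (n,):
            raise PlanValidationError(
                f"segment {self.index}: leaf arrays must have length {n}"
            )
        bad = np.nonzero(self.leaf_a_mm > self.leaf_b_mm)[0]
        if bad.size:
            raise PlanValidationError(
                f"segment {self.index}: leaf_a > leaf_b for pairs {bad.tolist()}"
            )
        if self.diaphragm_x1_mm > self.diaphragm_x2_mm:
            raise PlanValidationError(f"segment {self.index}: diaphragm x1 > x2")
        if self.diaphragm_y1_mm > self.diaphragm_y2_mm:
            raise PlanValidationError(f"segment {self.index}: diaphragm y1 > y2")


@dataclass
class BeamPlan:
    """An ordered sequence of step-and-shoot segments for one beam."""

    plan_id: str
    beam_id: str
    geometry: MachineGeometry
    segments: list[PlanSegment] = field(default_factory=list)
    total_mu: float = 0.0

    def validate(self) -> None:
        if not self.segments:
            raise PlanValidationError("plan has no segments")
        for k, seg in enumerate(self.segments):
            if seg.index != k:
                raise PlanValidationError(
                    f"segment indices not contiguous from 0 (got {seg.index} at {k})"
                )
            seg.validate(self.geometry)
        s = sum(seg.mu for seg in self.segments)
        if self.total_mu > 0 and abs(s - self.total_mu) > 1e-6 * max(1.0, self.total_mu):
            raise PlanValidationError(
                f"segment MUs sum to {s}, expected total_mu {self.total_mu}"
            )

    def copy(self) -> "BeamPlan":
        return BeamPlan(
            plan_id=self.plan_id,
            beam_id=self.beam_id,
            geometry=self.geometry,
            segments=[replace(s, leaf_a_mm=s.leaf_a_mm.copy(), leaf_b_mm=s.leaf_b_mm.copy())
                      for s in self.segments],
            total_mu=self.total_mu,
        )


def default_geometry(n_leaf_pairs: int = 80, leaf_width_mm: float = 7.0) -> MachineGeometry:
    """Fixture geometry: uniform-width leaf bank, parks at 130.0/134.0 mm."""
    return MachineGeometry(n_leaf_pairs=n_leaf_pairs, leaf_width_mm=leaf_width_mm)


def plans_equal(p1: BeamPlan, p2: BeamPlan, tol: float = 1e-9) -> bool:
    """Structural equality up to ``tol`` on floats (roundtrip checks)."""
    if (p1.plan_id, p1.beam_id) != (p2.plan_id, p2.beam_id):
        return False
    if p1.geometry != p2.geometry:
        return False
    if abs(p1.total_mu - p2.total_mu) > tol:
        return False
    if len(p1.segments) != len(p2.segments):
        return False
    for s1, s2 in zip(p1.segments, p2.segments):
        scalars1 = (s1.mu, s1.gantry_deg, s1.collimator_deg, s1.diaphragm_x1_mm,
                    s1.diaphragm_x2_mm, s1.diaphragm_y1_mm, s1.diaphragm_y2_mm)
        scalars2 = (s2.mu, s2.gantry_deg, s2.collimator_deg, s2.diaphragm_x1_mm,
                    s2.diaphragm_x2_mm, s2.diaphragm_y1_mm, s2.diaphragm_y2_mm)
        if any(abs(a - b) > tol for a, b in zip(scalars1, scalars2)):
            return False
        if not (np.allclose(s1.leaf_a_mm, s2.leaf_a_mm, rtol=0, atol=tol)
                and np.allclose(s1.leaf_b_mm, s2.leaf_b_mm, rtol=0, atol=tol)):
            return False
    return True


# ---------------------------------------------------------------------------
# Simple-plan JSON schema
# ---------------------------------------------------------------------------

_GEOMETRY_KEYS = {
    "n_leaf_pairs", "leaf_width_mm", "leaf_travel_axis",
    "max_field_x_mm", "max_field_y_mm", "park_positions_mm",
}


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise SchemaError(f"missing required key '{key}' in {where}")
    return mapping[key]


def _geometry_to_dict(g: MachineGeometry) -> dict:
    return {
        "n_leaf_pairs": g.n_leaf_pairs,
        "leaf_width_mm": g.leaf_width_mm,
        "leaf_travel_axis": g.leaf_travel_axis,
        "max_field_x_mm": g.max_field_x_mm,
        "max_field_y_mm": g.max_field_y_mm,
        "park_positions_mm": list(g.park_positions_mm),
    }


def geometry_from_dict(d: dict) -> MachineGeometry:
    if not isinstance(d, dict):
        raise SchemaError("'geometry' must be an object")
    unknown = set(d) - _GEOMETRY_KEYS
    if unknown:
        raise SchemaError(f"unknown geometry keys: {sorted(unknown)}")
    park = d.get("park_positions_mm", (130.0, 134.0))
    if len(park) != 2:
        raise SchemaError("'park_positions_mm' must have exactly 2 entries")
    try:
        return MachineGeometry(
            n_leaf_pairs=int(_require(d, "n_leaf_pairs", "geometry")),
            leaf_width_mm=float(_require(d, "leaf_width_mm", "geometry")),
            leaf_travel_axis=str(d.get("leaf_travel_axis", "X")),
            max_field_x_mm=float(d.get("max_field_x_mm", 240.0)),
            max_field_y_mm=float(d.get("max_field_y_mm", 560.0)),
            park_positions_mm=(float(park[0]), float(park[1])),
        )
    except PlanValidationError as exc:
        raise SchemaError(f"invalid geometry: {exc}") from exc


def plan_to_dict(plan: BeamPlan) -> dict:
    plan.validate()
    return {
        "format": SIMPLE_PLAN_FORMAT,
        "plan_id": plan.plan_id,
        "beam_id": plan.beam_id,
        "geometry": _geometry_to_dict(plan.geometry),
        "total_mu": plan.total_mu,
        "segments": [
            {
                "mu": seg.mu,
                "gantry_deg": seg.gantry_deg,
                "collimator_deg": seg.collimator_deg,
                "leaf_a_mm": seg.leaf_a_mm.tolist(),
                "leaf_b_mm": seg.leaf_b_mm.tolist(),
                "diaphragms": {
                    "x1": seg.diaphragm_x1_mm,
                    "x2": seg.diaphragm_x2_mm,
                    "y1": seg.diaphragm_y1_mm,
                    "y2": seg.diaphragm_y2_mm,
                },
            }
            for seg in plan.segments
        ],
    }


def plan_from_dict(doc: dict) -> BeamPlan:
    if not isinstance(doc, dict):
        raise SchemaError("plan document must be a JSON object")
    fmt = doc.get("format", SIMPLE_PLAN_FORMAT)
    if fmt != SIMPLE_PLAN_FORMAT:
        raise SchemaError(f"unsupported plan format '{fmt}'")
    geometry = geometry_from_dict(_require(doc, "geometry", "plan"))
    raw_segments = _require(doc, "segments", "plan")
    if not isinstance(raw_segments, list) or not raw_segments:
        raise SchemaError("'segments' must be a non-empty list")
    segments = []
    for k, s in enumerate(raw_segments):
        where = f"segments[{k}]"
        dia = _require(s, "diaphragms", where)
        for dk in ("x1", "x2", "y1", "y2"):
            _require(dia, dk, f"{where}.diaphragms")
        segments.append(
            PlanSegment(
                index=k,
                mu=float(_require(s, "mu", where)),
                gantry_deg=float(s.get("gantry_deg", 0.0)),
                collimator_deg=float(s.get("collimator_deg", 0.0)),
                leaf_a_mm=np.asarray(_require(s, "leaf_a_mm", where), dtype=float),
                leaf_b_mm=np.asarray(_require(s, "leaf_b_mm", where), dtype=float),
                diaphragm_x1_mm=float(dia["x1"]),
                diaphragm_x2_mm=float(dia["x2"]),
                diaphragm_y1_mm=float(dia["y1"]),
                diaphragm_y2_mm=float(dia["y2"]),
            )
        )
    plan = BeamPlan(
        plan_id=str(_require(doc, "plan_id", "plan")),
        beam_id=str(_require(doc, "beam_id", "plan")),
        geometry=geometry,
        segments=segments,
        total_mu=float(_require(doc, "total_mu", "plan")),
    )
    try:
        plan.validate()
    except PlanValidationError as exc:
        raise SchemaError(str(exc)) from exc
    return plan


def read_simple_plan(path: str | Path) -> BeamPlan:
    """Read a plan from the documented simple-plan JSON schema."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"not valid JSON: {exc}") from exc
    return plan_from_dict(doc)


def write_simple_plan(plan: BeamPlan, path: str | Path) -> None:
    """Write a plan in the simple-plan JSON schema (roundtrip-exact floats)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(plan_to_dict(plan), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# DICOM RT Plan
# ---------------------------------------------------------------------------


class RTPlanParseError(ValueError):
    """A DICOM RT Plan is missing attributes or uses an unsupported delivery."""


def _leaf_boundaries(geometry: MachineGeometry) -> list[float]:
    half = geometry.bank_span_mm / 2.0
    return [-half + i * geometry.leaf_width_mm for i in range(geometry.n_leaf_pairs + 1)]


def write_rtplan(plans: Sequence[BeamPlan], path: str | Path) -> None:
    """Write beams as a minimal static (step-and-shoot) DICOM RT Plan.

    The segment held over MU interval *k* is encoded on control point *k*
    with cumulative meterset weights; the final control point carries only
    the terminal weight 1.0.  All beams must share a plan_id.
    """
    if not plans:
        raise PlanValidationError("no beams to write")
    for p in plans:
        p.validate()

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = RTPLAN_SOP_CLASS_UID
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = RTPLAN_SOP_CLASS_UID
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plans[0].plan_id
    ds.RTPlanGeometry = "TREATMENT_DEVICE"

    fraction_group = Dataset()
    fraction_group.FractionGroupNumber = 1
    fraction_group.NumberOfFractionsPlanned = 1
    fraction_group.NumberOfBeams = len(plans)
    fraction_group.ReferencedBeamSequence = []

    ds.BeamSequence = []
    for beam_number, plan in enumerate(plans, start=1):
        g = plan.geometry
        beam = Dataset()
        beam.BeamNumber = beam_number
        beam.BeamName = plan.beam_id
        beam.BeamType = "STATIC"
        beam.RadiationType = "PHOTON"
        beam.TreatmentDeliveryType = "TREATMENT"
        beam.NumberOfControlPoints = len(plan.segments) + 1

        mlc_device = Dataset()
        mlc_device.RTBeamLimitingDeviceType = "MLCX"
        mlc_device.NumberOfLeafJawPairs = g.n_leaf_pairs
        mlc_device.LeafPositionBoundaries = [f"{b:.6f}" for b in _leaf_boundaries(g)]
        x_device = Dataset()
        x_device.RTBeamLimitingDeviceType = "ASYMX"
        x_device.NumberOfLeafJawPairs = 1
        y_device = Dataset()
        y_device.RTBeamLimitingDeviceType = "ASYMY"
        y_device.NumberOfLeafJawPairs = 1
        beam.BeamLimitingDeviceSequence = [x_device, y_device, mlc_device]

        cps = []
        cum = 0.0
        for seg in plan.segments:
            cp = Dataset()
            cp.ControlPointIndex = seg.index
            cp.CumulativeMetersetWeight = cum / plan.total_mu if plan.total_mu else 0.0
            cp.GantryAngle = seg.gantry_deg
            cp.BeamLimitingDeviceAngle = seg.collimator_deg
            x_pos = Dataset()
            x_pos.RTBeamLimitingDeviceType = "ASYMX"
            x_pos.LeafJawPositions = [seg.diaphragm_x1_mm, seg.diaphragm_x2_mm]
            y_pos = Dataset()
            y_pos.RTBeamLimitingDeviceType = "ASYMY"
            y_pos.LeafJawPositions = [seg.diaphragm_y1_mm, seg.diaphragm_y2_mm]
            mlc_pos = Dataset()
            mlc_pos.RTBeamLimitingDeviceType = "MLCX"
            mlc_pos.LeafJawPositions = (
                seg.leaf_a_mm.tolist() + seg.leaf_b_mm.tolist()
            )
            cp.BeamLimitingDevicePositionSequence = [x_pos, y_pos, mlc_pos]
            cps.append(cp)
            cum += seg.mu
        final_cp = Dataset()
        final_cp.ControlPointIndex = len(plan.segments)
        final_cp.CumulativeMetersetWeight = 1.0
        cps.append(final_cp)
        beam.ControlPointSequence = cps
        beam.FinalCumulativeMetersetWeight = 1.0
        ds.BeamSequence.append(beam)

        ref_beam = Dataset()
        ref_beam.ReferencedBeamNumber = beam_number
        ref_beam.BeamMeterset = plan.total_mu
        fraction_group.ReferencedBeamSequence.append(ref_beam)

    ds.FractionGroupSequence = [fraction_group]
    pydicom.dcmwrite(path, ds, enforce_file_format=True)


def _get(ds: Dataset, attr: str, where: str):
    if not hasattr(ds, attr):
        raise RTPlanParseError(f"missing attribute '{attr}' in {where}")
    return getattr(ds, attr)


def read_rtplan(
    path: str | Path,
    geometry: MachineGeometry | None = None,
) -> list[BeamPlan]:
    """Read a static (step-and-shoot) DICOM RT Plan into BeamPlans.

    Cumulative meterset weights are converted to per-segment MU using the
    beam meterset from the fraction-group's ReferencedBeamSequence.  When
    ``geometry`` is omitted it is reconstructed from the MLC leaf-position
    boundaries (requires uniform leaf width).
    """
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTPLAN":
        raise RTPlanParseError(f"not an RT Plan (Modality={getattr(ds, 'Modality', None)!r})")
    plan_id = str(getattr(ds, "RTPlanLabel", getattr(ds, "SOPInstanceUID", "unknown")))

    metersets: dict[int, float] = {}
    for fg in _get(ds, "FractionGroupSequence", "dataset"):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if hasattr(rb, "BeamMeterset"):
                metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    plans: list[BeamPlan] = []
    for beam in _get(ds, "BeamSequence", "dataset"):
        beam_number = int(_get(beam, "BeamNumber", "beam"))
        where = f"beam {beam_number}"
        beam_type = str(_get(beam, "BeamType", where))
        if beam_type != "STATIC":
            raise RTPlanParseError(
                f"{where}: dynamic (interpolated) delivery is unsupported "
                f"(BeamType={beam_type!r})"
            )
        if beam_number not in metersets:
            raise RTPlanParseError(f"{where}: no BeamMeterset in FractionGroupSequence")
        beam_meterset = metersets[beam_number]

        geom = geometry
        if geom is None:
            geom = _geometry_from_beam(beam, where)

        cps = list(_get(beam, "ControlPointSequence", where))
        if len(cps) < 2:
            raise RTPlanParseError(f"{where}: needs >= 2 control points")
        weights = []
        for cp in cps:
            weights.append(float(_get(cp, "CumulativeMetersetWeight", f"{where} control point")))

        # carry machine state forward across control points that omit it
        state: dict = {"gantry": None, "collimator": None,
                       "x": None, "y": None, "mlc": None}
        segments: list[PlanSegment] = []
        for k, cp in enumerate(cps[:-1]):
            _update_state(state, cp)
            for key, label in (("gantry", "GantryAngle"), ("x", "ASYMX jaws"),
                               ("y", "ASYMY jaws"), ("mlc", "MLCX positions")):
                if state[key] is None:
                    raise RTPlanParseError(f"{where} control point {k}: missing {label}")
            mu = (weights[k + 1] - weights[k]) * beam_meterset
            n = geom.n_leaf_pairs
            mlc = np.asarray(state["mlc"], dtype=float)
            if mlc.size != 2 * n:
                raise RTPlanParseError(
                    f"{where} control point {k}: expected {2*n} MLC values, got {mlc.size}"
                )
            segments.append(
                PlanSegment(
                    index=k,
                    mu=mu,
                    gantry_deg=float(state["gantry"]) % 360.0,
                    collimator_deg=float(state["collimator"] or 0.0),
                    leaf_a_mm=mlc[:n],
                    leaf_b_mm=mlc[n:],
                    diaphragm_x1_mm=float(state["x"][0]),
                    diaphragm_x2_mm=float(state["x"][1]),
                    diaphragm_y1_mm=float(state["y"][0]),
                    diaphragm_y2_mm=float(state["y"][1]),
                )
            )
        plan = BeamPlan(
            plan_id=plan_id,
            beam_id=str(getattr(beam, "BeamName", beam_number)),
            geometry=geom,
            segments=segments,
            total_mu=beam_meterset,
        )
        plan.validate()
        plans.append(plan)
    return plans


def _geometry_from_beam(beam: Dataset, where: str) -> MachineGeometry:
    for dev in getattr(beam, "BeamLimitingDeviceSequence", []):
        if str(dev.RTBeamLimitingDeviceType).startswith("MLC"):
            bounds = np.asarray([float(v) for v in dev.LeafPositionBoundaries])
            widths = np.diff(bounds)
            if not np.allclose(widths, widths[0], atol=1e-6):
                raise RTPlanParseError(f"{where}: non-uniform leaf widths unsupported")
            return MachineGeometry(
                n_leaf_pairs=len(widths), leaf_width_mm=float(widths[0])
            )
    raise RTPlanParseError(f"{where}: no MLC in BeamLimitingDeviceSequence")


def _update_state(state: dict, cp: Dataset) -> None:
    if hasattr(cp, "GantryAngle"):
        state["gantry"] = float(cp.GantryAngle)
    if hasattr(cp, "BeamLimitingDeviceAngle"):
        state["collimator"] = float(cp.BeamLimitingDeviceAngle)
    for pos in getattr(cp, "BeamLimitingDevicePositionSequence", []):
        kind = str(pos.RTBeamLimitingDeviceType)
        vals = [float(v) for v in pos.LeafJawPositions]
        if kind in ("X", "ASYMX"):
            state["x"] = vals
        elif kind in ("Y", "ASYMY"):
            state["y"] = vals
        elif kind.startswith("MLC"):
            state["mlc"] = vals
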