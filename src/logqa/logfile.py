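"""Delivery-log model and CSV dialect.

A delivery log is the time series a log-file listener records during one beam
delivery: cumulative MU, gantry/collimator angles, couch coordinates,
diaphragm (jaw) edges and every leaf position, sampled at a nominal rate
(default 4 Hz).  The on-disk format is a documented plain-text CSV dialect:

    line 1:  ``#logqa-log v1``
    line 2:  JSON metadata ``{"plan_id":…, "beam_id":…, "n_leaf_pairs":…,
             "sample_rate_hz":…}``
    line 3:  column names ``t_s,mu_cum,gantry_deg,collimator_deg,
             couch_lat_mm,couch_long_mm,couch_vert_mm,
             dia_x1_mm,dia_x2_mm,dia_y1_mm,dia_y2_mm,
             a000..a{N-1},b000..b{N-1},beam_on``
    line 4+: one record per line; floats via ``repr`` (shortest exact
             roundtrip, always >= 6 significant digits); beam_on as 0/1.

Timestamps are elapsed seconds from beam load, not wall clock, so fixture
logs are deterministic.  Records are stored columnar (numpy arrays) for
analysis speed; :class:`LogRecord` offers a per-record view.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .rtplan import MachineGeometry

__all__ = [
    "LogRecord",
    "DeliveryLog",
    "LogValidationError",
    "LogParseError",
    "read_log",
    "write_log",
    "log_to_string",
    "log_from_string",
    "is_complete",
]

LOG_FORMAT = "#logqa-log v1"

_SCALAR_COLUMNS = (
    "t_s", "mu_cum", "gantry_deg", "collimator_deg",
    "couch_lat_mm", "couch_long_mm", "couch_vert_mm",
    "dia_x1_mm", "dia_x2_mm", "dia_y1_mm", "dia_y2_mm",
)


class LogValidationError(ValueError):
    """A delivery log violates a structural invariant."""


class LogParseError(ValueError):
    """A log file does not conform to the documented CSV dialect."""


@dataclass(frozen=True)
class LogRecord:
    """One listener sample (a read-only view into a DeliveryLog row)."""

    t_s: float
    mu_cum: float
    gantry_deg: float
    collimator_deg: float
    couch_lat_mm: float
    couch_long_mm: float
    couch_vert_mm: float
    diaphragm_x1_mm: float
    diaphragm_x2_mm: float
    diaphragm_y1_mm: float
    diaphragm_y2_mm: float
    leaf_a_mm: np.ndarray
    leaf_b_mm: np.ndarray
    beam_on: bool


@dataclass
class DeliveryLog:
    """Columnar time series of delivered machine state for one beam.

    ``leaf_a_mm``/``leaf_b_mm`` are (n_records, n_leaf_pairs) arrays; the
    scalar channels are 1-D arrays of length n_records.
    """

    plan_id: str
    beam_id: str
    geometry: MachineGeometry
    sample_rate_hz: float = 4.0
    t_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    mu_cum: np.ndarray = field(default_factory=lambda: np.empty(0))
    gantry_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    collimator_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    couch_lat_mm: np.ndarray = field(default_factory=lambda: np.empty(0))
    couch_long_mm: np.ndarray = field(default_factory=lambda: np.empty(0))
    couch_vert_mm: np.ndarray = field(default_factory=lambda: np.empty(0))
    dia_x1_mm: np.ndarray = field(default_factory=lambda: np.empty(0))
    dia_x2_mm: np.ndarray = field(default_factory=lambda: np.empty(0))
    dia_y1_mm: np.ndarray = field(default_factory=lambda: np.empty(0))
    dia_y2_mm: np.ndarray = field(default_factory=lambda: np.empty(0))
    leaf_a_mm: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    leaf_b_mm: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    beam_on: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    @property
    def n_records(self) -> int:
        return len(self.t_s)

    def record(self, i: int) -> LogRecord:
        return LogRecord(
            t_s=float(self.t_s[i]), mu_cum=float(self.mu_cum[i]),
            gantry_deg=float(self.gantry_deg[i]),
            collimator_deg=float(self.collimator_deg[i]),
            couch_lat_mm=float(self.couch_lat_mm[i]),
            couch_long_mm=float(self.couch_long_mm[i]),
            couch_vert_mm=float(self.couch_vert_mm[i]),
            diaphragm_x1_mm=float(self.dia_x1_mm[i]),
            diaphragm_x2_mm=float(self.dia_x2_mm[i]),
            diaphragm_y1_mm=float(self.dia_y1_mm[i]),
            diaphragm_y2_mm=float(self.dia_y2_mm[i]),
            leaf_a_mm=self.leaf_a_mm[i].copy(),
            leaf_b_mm=self.leaf_b_mm[i].copy(),
            beam_on=bool(self.beam_on[i]),
        )

    @property
    def records(self) -> list[LogRecord]:
        return [self.record(i) for i in range(self.n_records)]

    def validate(self) -> None:
        n = self.n_records
        if n < 2:
            raise LogValidationError("log must have >= 2 records")
        dt = np.diff(self.t_s)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise LogValidationError(
                f"time not strictly increasing at record {int(bad[0]) + 2}"
            )
        dmu = np.diff(self.mu_cum)
        bad = np.nonzero(dmu < -1e-12)[0]
        if bad.size:
            raise LogValidationError(
                f"cumulative MU decreasing at record {int(bad[0]) + 2}"
            )
        npairs = self.geometry.n_leaf_pairs
        if self.leaf_a_mm.shape != (n, npairs) or self.leaf_b_mm.shape != (n, npairs):
            raise LogValidationError(
                f"leaf arrays must have shape ({n}, {npairs})"
            )
        median_dt = float(np.median(dt))
        nominal = 1.0 / self.sample_rate_hz
        if not math.isclose(median_dt, nominal, rel_tol=0.2):
            raise LogValidationError(
                f"median inter-record interval {median_dt:.4f} s deviates more than "
                f"20% from nominal {nominal:.4f} s"
            )


def is_complete(log: DeliveryLog, holdoff_s: float = 2.0) -> bool:
    """True when the beam has been off for at least ``holdoff_s`` at log end.

    This is the streaming-completeness contract: a listener appending records
    incrementally declares the log complete once ``beam_on`` falls and stays
    false for the hold-off period.
    """
    if log.n_records < 2 or bool(log.beam_on[-1]):
        return False
    off = np.nonzero(log.beam_on)[0]
    last_on = int(off[-1]) if off.size else -1
    t_off_start = float(log.t_s[last_on + 1]) if last_on + 1 < log.n_records else None
    if t_off_start is None:
        return False
    return float(log.t_s[-1]) - t_off_start >= holdoff_s - 1e-9


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


def _columns(n_pairs: int) -> list[str]:
    cols = list(_SCALAR_COLUMNS)
    cols += [f"a{i:03d}" for i in range(n_pairs)]
    cols += [f"b{i:03d}" for i in range(n_pairs)]
    cols.append("beam_on")
    return cols


def log_to_string(log: DeliveryLog) -> str:
    """Serialize a log in the documented CSV dialect (deterministic)."""
    log.validate()
    n_pairs = log.geometry.n_leaf_pairs
    meta = {
        "plan_id": log.plan_id,
        "beam_id": log.beam_id,
        "n_leaf_pairs": n_pairs,
        "sample_rate_hz": log.sample_rate_hz,
        "geometry": {
            "leaf_width_mm": log.geometry.leaf_width_mm,
            "leaf_travel_axis": log.geometry.leaf_travel_axis,
            "max_field_x_mm": log.geometry.max_field_x_mm,
            "max_field_y_mm": log.geometry.max_field_y_mm,
            "park_positions_mm": list(log.geometry.park_positions_mm),
        },
    }
    buf = io.StringIO()
    buf.write(LOG_FORMAT + "\n")
    buf.write(json.dumps(meta, sort_keys=True) + "\n")
    buf.write(",".join(_columns(n_pairs)) + "\n")
    scalars = [getattr(log, c if c != "t_s" else "t_s") for c in _SCALAR_COLUMNS]
    for i in range(log.n_records):
        parts = [repr(float(col[i])) for col in scalars]
        parts += [repr(float(v)) for v in log.leaf_a_mm[i]]
        parts += [repr(float(v)) for v in log.leaf_b_mm[i]]
        parts.append("1" if log.beam_on[i] else "0")
        buf.write(",".join(parts) + "\n")
    return buf.getvalue()


def write_log(log: DeliveryLog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(log_to_string(log))


def log_from_string(text: str, validate: bool = True) -> DeliveryLog:
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise LogParseError("no records: empty file")
    if lines[0].strip() != LOG_FORMAT:
        raise LogParseError(f"bad format line {lines[0]!r}, expected {LOG_FORMAT!r}")
    if len(lines) < 3:
        raise LogParseError("truncated header (need 3 header lines)")
    try:
        meta = json.loads(lines[1])
    except json.JSONDecodeError as exc:
        raise LogParseError(f"metadata line is not valid JSON: {exc}") from exc
    for key in ("plan_id", "beam_id", "n_leaf_pairs", "sample_rate_hz"):
        if key not in meta:
            raise LogParseError(f"metadata missing key '{key}'")
    n_pairs = int(meta["n_leaf_pairs"])
    expected_cols = _columns(n_pairs)
    header = lines[2].split(",")
    if header != expected_cols:
        raise LogParseError(
            f"column header does not match geometry ({len(header)} columns, "
            f"expected {len(expected_cols)})"
        )
    data_lines = [ln for ln in lines[3:] if ln.strip()]
    if not data_lines:
        raise LogParseError("no records")
    try:
        data = np.loadtxt(io.StringIO("\n".join(data_lines)), delimiter=",", ndmin=2)
    except ValueError as exc:
        raise LogParseError(f"malformed record: {exc}") from exc
    if data.shape[1] != len(expected_cols):
        raise LogParseError(
            f"column-count mismatch: rows have {data.shape[1]} fields, header has "
            f"{len(expected_cols)}"
        )

    gmeta = meta.get("geometry", {})
    geometry = MachineGeometry(
        n_leaf_pairs=n_pairs,
        leaf_width_mm=float(gmeta.get("leaf_width_mm", 7.0)),
        leaf_travel_axis=str(gmeta.get("leaf_travel_axis", "X")),
        max_field_x_mm=float(gmeta.get("max_field_x_mm", 240.0)),
        max_field_y_mm=float(gmeta.get("max_field_y_mm", 560.0)),
        park_positions_mm=tuple(gmeta.get("park_positions_mm", (130.0, 134.0))),
    )
    ns = len(_SCALAR_COLUMNS)
    log = DeliveryLog(
        plan_id=str(meta["plan_id"]),
        beam_id=str(meta["beam_id"]),
        geometry=geometry,
        sample_rate_hz=float(meta["sample_rate_hz"]),
        t_s=data[:, 0], mu_cum=data[:, 1],
        gantry_deg=data[:, 2], collimator_deg=data[:, 3],
        couch_lat_mm=data[:, 4], couch_long_mm=data[:, 5], couch_vert_mm=data[:, 6],
        dia_x1_mm=data[:, 7], dia_x2_mm=data[:, 8],
        dia_y1_mm=data[:, 9], dia_y2_mm=data[:, 10],
        leaf_a_mm=data[:, ns:ns + n_pairs],
        leaf_b_mm=data[:, ns + n_pairs:ns + 2 * n_pairs],
        beam_on=data[:, -1] > 0.5,
    )
    if validate:
        log.validate()
    return log


def read_log(path: str | Path, validate: bool = True) -> DeliveryLog:
    """Read a delivery log from the documented CSV dialect.

    The reader tolerates incremental appends: re-reading a growing file
    parses whatever complete records are present; use :func:`is_complete`
    to decide when a delivery has finished.
    """
    with open(path, "r", encoding="utf-8") as fh:
        return log_from_string(fh.read(), validate=validate)


def logs_equal(l1: DeliveryLog, l2: DeliveryLog, tol: float = 1e-9) -> bool:
    """Structural equality up to ``tol`` on floats (roundtrip checks)."""
    if (l1.plan_id, l1.beam_id) != (l2.plan_id, l2.beam_id):
        return False
    if l1.geometry != l2.geometry or l1.sample_rate_hz != l2.sample_rate_hz:
        return False
    if l1.n_records != l2.n_records:
        return False
    arrays = ("t_s", "mu_cum", "gantry_deg", "collimator_deg", "couch_lat_mm",
              "couch_long_mm", "couch_vert_mm", "dia_x1_mm", "dia_x2_mm",
              "dia_y1_mm", "dia_y2_mm", "leaf_a_mm", "leaf_b_mm")
    for name in arrays:
        if not np.allclose(getattr(l1, name), getattr(l2, name), rtol=0, atol=tol):
            return False
    return bool(np.array_equal(l1.beam_on, l2.beam_on))
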