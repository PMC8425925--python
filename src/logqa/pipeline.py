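"""Automated QA workflow: match plans with logs, analyze, report, alert.

The workflow mirrors an automated clinical loop: plans are exported to a
watched directory, a listener drops delivery logs into another; once a
matching (plan, log) pair is present and the log is complete, the analysis
runs immediately -- planned vs delivered fluence scored with the gamma
index, plus positional (TG-142-style) checks -- and a JSON report is
written.  A failing or erroring report fires a pluggable alert hook (an
alert file by default, optionally a user command), standing in for the
warning e-mail of a hospital deployment.

Everything is deterministic given inputs and configuration; wall-clock
timestamps are isolated in a single report field so reports are otherwise
byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import shlex
import subprocess
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .fluence import (
    FluenceError, FluenceGrid, FluenceMap, _effective_bounds, auto_grid,
    extract_segments_detailed, plan_fluence, rasterize_aperture,
)
from .gammaindex import GammaCriteria, GammaError, gamma_map
from .logfile import DeliveryLog, LogParseError, LogValidationError, is_complete, log_to_string, read_log
from .positional import TOLERANCE_PROFILES, ToleranceSet, positional_report
from .rtplan import (
    BeamPlan, PlanValidationError, SchemaError, plan_to_dict, read_rtplan,
    read_simple_plan,
)
from .simulate import DEFAULT_CLOSED_GAP_MM

__all__ = [
    "QAConfig",
    "QAReport",
    "MatchResult",
    "match_plan_log",
    "analyze",
    "notify",
    "Watcher",
    "watch",
]

logger = logging.getLogger("logqa")


@dataclass
class QAConfig:
    """Pipeline configuration (gamma criteria, tolerances, paths, alerting)."""

    criteria: GammaCriteria = field(default_factory=GammaCriteria)
    tolerances: ToleranceSet = field(default_factory=ToleranceSet)
    alert_gamma_t_pct: float = 90.0
    grid_spacing_mm: float = 1.0
    stationarity_tol_mm: float = 0.3
    min_segment_mu: float = 0.1
    guard_pairs: int = 1
    closed_gap_mm: float = DEFAULT_CLOSED_GAP_MM
    plan_dir: str | None = None
    log_dir: str | None = None
    report_dir: str | None = None
    alert_dir: str | None = None
    alert_command: str | None = None
    holdoff_s: float = 2.0
    pending_timeout_s: float = 300.0
    phase: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.alert_gamma_t_pct < 100.0:
            raise ValueError("alert threshold must be in (0, 100)")

    def to_dict(self) -> dict:
        return {
            "criteria": {
                "dose_tol_pct": self.criteria.dose_tol_pct,
                "dta_mm": self.criteria.dta_mm,
                "low_threshold_pct": self.criteria.low_threshold_pct,
                "normalization": self.criteria.normalization,
            },
            "tolerances": {
                "gantry_deg": self.tolerances.gantry_deg,
                "jaw_mm": self.tolerances.jaw_mm,
                "mlc_mm": self.tolerances.mlc_mm,
                "collimator_deg": self.tolerances.collimator_deg,
            },
            "alert_gamma_t_pct": self.alert_gamma_t_pct,
            "grid_spacing_mm": self.grid_spacing_mm,
            "stationarity_tol_mm": self.stationarity_tol_mm,
            "min_segment_mu": self.min_segment_mu,
            "guard_pairs": self.guard_pairs,
            "closed_gap_mm": self.closed_gap_mm,
            "phase": self.phase,
        }

    @classmethod
    def from_file(cls, path: str | Path) -> "QAConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        crit = doc.pop("criteria", {})
        tolname = doc.pop("tolerance_profile", None)
        tols = doc.pop("tolerances", None)
        if tolname is not None:
            tolerances = TOLERANCE_PROFILES[tolname]
        elif tols is not None:
            tolerances = ToleranceSet(**{k: v for k, v in tols.items() if v is not None})
        else:
            tolerances = ToleranceSet()
        return cls(criteria=GammaCriteria(**crit), tolerances=tolerances, **doc)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    matched: list[tuple[BeamPlan, DeliveryLog]]
    unmatched_plans: list[BeamPlan]
    unmatched_logs: list[DeliveryLog]
    ambiguous: list[str]


def match_plan_log(plans: list[BeamPlan], logs: list[DeliveryLog]) -> MatchResult:
    """Pair plans with logs on (plan_id, beam_id); never guess.

    Keys claimed by more than one plan or more than one log are flagged
    ambiguous and excluded from the matched list.
    """
    plan_keys: dict[tuple[str, str], list[BeamPlan]] = {}
    for p in plans:
        plan_keys.setdefault((p.plan_id, p.beam_id), []).append(p)
    log_keys: dict[tuple[str, str], list[DeliveryLog]] = {}
    for lg in logs:
        log_keys.setdefault((lg.plan_id, lg.beam_id), []).append(lg)

    matched, ambiguous = [], []
    unmatched_plans, unmatched_logs = [], []
    for key, ps in plan_keys.items():
        ls = log_keys.get(key, [])
        if len(ps) > 1 or len(ls) > 1:
            ambiguous.append(f"plan_id={key[0]} beam_id={key[1]}: "
                             f"{len(ps)} plans, {len(ls)} logs")
        elif ls:
            matched.append((ps[0], ls[0]))
        else:
            unmatched_plans.extend(ps)
    for key, ls in log_keys.items():
        if key not in plan_keys:
            unmatched_logs.extend(ls)
    return MatchResult(matched, unmatched_plans, unmatched_logs, ambiguous)


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------


@dataclass
class QAReport:
    """Result of one plan-vs-log analysis, JSON-serializable."""

    plan_id: str
    beam_id: str
    verdict: str  # "pass" | "fail" | "error"
    reasons: list[str]
    gamma: dict
    positional: dict
    provenance: dict
    timestamps: dict

    def to_dict(self) -> dict:
        return {
            "plan_id": self.plan_id,
            "beam_id": self.beam_id,
            "verdict": self.verdict,
            "reasons": self.reasons,
            "gamma": self.gamma,
            "positional": self.positional,
            "provenance": self.provenance,
            "timestamps": self.timestamps,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def analysis_grid(plan: BeamPlan, segments, config: QAConfig,
                  delivered_geometry=None) -> FluenceGrid:
    """Grid covering the plan's apertures *and* the delivered apertures, so
    a grossly wrong delivery (e.g. the wrong plan's log) still rasterizes
    and is scored instead of erroring out.  ``delivered_geometry`` is the
    log's machine geometry (defaults to the plan's)."""
    geometry = delivered_geometry or plan.geometry
    grid = auto_grid(plan, spacing_mm=config.grid_spacing_mm)
    xmin, xmax = grid.x_extent
    ymin, ymax = grid.y_extent
    for seg in segments:
        bounds = _effective_bounds(
            seg.leaf_a_mm, seg.leaf_b_mm,
            seg.diaphragm_x1_mm, seg.diaphragm_x2_mm,
            seg.diaphragm_y1_mm, seg.diaphragm_y2_mm,
            geometry,
        )
        if bounds is None:
            continue
        xmin = min(xmin, bounds[0] - 10.0)
        xmax = max(xmax, bounds[1] + 10.0)
        ymin = min(ymin, bounds[2] - 10.0)
        ymax = max(ymax, bounds[3] + 10.0)
    s = config.grid_spacing_mm
    x0 = math.floor(xmin / s) * s
    y0 = math.floor(ymin / s) * s
    return FluenceGrid(
        origin_x_mm=x0 + s / 2.0, origin_y_mm=y0 + s / 2.0, spacing_mm=s,
        nx=math.ceil((xmax - x0) / s), ny=math.ceil((ymax - y0) / s),
    )


def analyze(
    plan: BeamPlan,
    log: DeliveryLog,
    config: QAConfig | None = None,
    plan_path: str | Path | None = None,
    log_path: str | Path | None = None,
) -> QAReport:
    """Run the full log-file QA of one delivery against its plan.

    Deterministic given inputs and config.  Any stage failure yields a
    report with verdict ``"error"`` and the stage's message -- a field is
    never silently dropped.
    """
    config = config or QAConfig()
    timestamps = {"analyzed_at": datetime.now(timezone.utc).isoformat()}
    provenance = {
        "software": f"logqa {__version__}",
        "config": config.to_dict(),
        "plan_digest": _sha256_file(plan_path) if plan_path
        else _sha256_text(json.dumps(plan_to_dict(plan), sort_keys=True)),
        "log_digest": _sha256_file(log_path) if log_path
        else _sha256_text(log_to_string(log)),
        "phase": config.phase,
    }
    reasons: list[str] = []
    gamma_summary: dict = {}
    positional_summary: dict = {}
    try:
        segments, n_discarded = extract_segments_detailed(
            log, config.stationarity_tol_mm, config.min_segment_mu
        )
        grid = analysis_grid(plan, segments, config,
                             delivered_geometry=log.geometry)
        reference = plan_fluence(plan, grid)
        delivered = FluenceMap(grid, np.zeros((grid.ny, grid.nx)))
        for seg in segments:
            delivered = delivered + rasterize_aperture(
                seg.leaf_a_mm, seg.leaf_b_mm,
                (seg.diaphragm_x1_mm, seg.diaphragm_x2_mm,
                 seg.diaphragm_y1_mm, seg.diaphragm_y2_mm),
                seg.mu, log.geometry, grid,
            )
        result = gamma_map(reference, delivered, config.criteria)
        gamma_summary = {
            "criteria": f"{config.criteria.dose_tol_pct:g}%,"
                        f"{config.criteria.dta_mm:g}mm",
            "pass_rate_pct": result.pass_rate_pct,
            "n_included": result.n_included,
            "n_passed": result.n_passed,
            "n_delivered_segments": len(segments),
            "n_discarded_segments": n_discarded,
        }
        geometry_ok = (
            log.geometry.n_leaf_pairs == plan.geometry.n_leaf_pairs
            and log.geometry.leaf_width_mm == plan.geometry.leaf_width_mm
        )
        pos = None
        if geometry_ok:
            pos = positional_report(
                plan, segments, config.tolerances,
                guard_pairs=config.guard_pairs, closed_gap_mm=config.closed_gap_mm,
            )
            positional_summary = pos.summary()
        else:
            positional_summary = {"geometry_mismatch": True}

        if result.pass_rate_pct < config.alert_gamma_t_pct:
            reasons.append(
                f"gamma pass rate {result.pass_rate_pct:.1f}% below alert "
                f"threshold {config.alert_gamma_t_pct:.1f}%"
            )
        if not geometry_ok:
            reasons.append(
                f"geometry mismatch: plan has {plan.geometry.n_leaf_pairs} "
                f"pairs of {plan.geometry.leaf_width_mm:g} mm, log has "
                f"{log.geometry.n_leaf_pairs} pairs of "
                f"{log.geometry.leaf_width_mm:g} mm"
            )
        if pos is not None:
            if pos.segment_count_mismatch:
                reasons.append(
                    f"segment-count mismatch: plan has {pos.n_plan_segments}, "
                    f"delivery has {pos.n_delivered_segments}"
                )
            for name, ok in (("gantry", pos.gantry_pass), ("jaw", pos.jaw_pass),
                             ("mlc", pos.mlc_pass)):
                if not ok:
                    reasons.append(f"{name} deviation beyond tolerance")
            if pos.collimator_pass is False:
                reasons.append("collimator deviation beyond tolerance")
        verdict = "fail" if reasons else "pass"
    except (FluenceError, GammaError, LogValidationError, PlanValidationError,
            ValueError) as exc:
        verdict = "error"
        reasons = [f"{type(exc).__name__}: {exc}"]

    return QAReport(
        plan_id=plan.plan_id,
        beam_id=plan.beam_id,
        verdict=verdict,
        reasons=reasons,
        gamma=gamma_summary,
        positional=positional_summary,
        provenance=provenance,
        timestamps=timestamps,
    )


# ---------------------------------------------------------------------------
# Alerts
# ---------------------------------------------------------------------------


def notify(
    report: QAReport,
    alert_dir: str | Path | None = None,
    alert_command: str | None = None,
    report_path: str | Path | None = None,
) -> dict:
    """Fire the alert hook iff the verdict is fail or error.

    Default hook writes an alert JSON into ``alert_dir``; an optional user
    command is invoked with the report path appended.  Hook failures are
    logged and recorded, never raised.
    """
    attempt = {
        "plan_id": report.plan_id,
        "beam_id": report.beam_id,
        "verdict": report.verdict,
        "fired": report.verdict in ("fail", "error"),
        "deliveries": [],
    }
    if not attempt["fired"]:
        return attempt
    if alert_dir is not None:
        try:
            alert_dir = Path(alert_dir)
            alert_dir.mkdir(parents=True, exist_ok=True)
            digest = report.provenance.get("log_digest", "na")[:12]
            path = alert_dir / f"alert_{report.plan_id}_{report.beam_id}_{digest}.json"
            path.write_text(report.to_json(), encoding="utf-8")
            attempt["deliveries"].append({"hook": "file", "ok": True, "path": str(path)})
        except OSError as exc:
            logger.error("alert file hook failed: %s", exc)
            attempt["deliveries"].append({"hook": "file", "ok": False, "error": str(exc)})
    if alert_command is not None:
        argv = shlex.split(alert_command) + ([str(report_path)] if report_path else [])
        try:
            proc = subprocess.run(argv, capture_output=True, timeout=30)
            ok = proc.returncode == 0
            if not ok:
                logger.error("alert command failed (rc=%d): %s",
                             proc.returncode, proc.stderr.decode(errors="replace"))
            attempt["deliveries"].append(
                {"hook": "command", "ok": ok, "returncode": proc.returncode})
        except (OSError, subprocess.SubprocessError) as exc:
            logger.error("alert command failed: %s", exc)
            attempt["deliveries"].append({"hook": "command", "ok": False, "error": str(exc)})
    return attempt


# ---------------------------------------------------------------------------
# Directory watcher (polling)
# ---------------------------------------------------------------------------


class Watcher:
    """Poll plan/log directories and analyze each complete pair exactly once.

    Idempotency is keyed on the (plan digest, log digest) pair and persisted
    to ``processed.json`` in the report directory, so re-dropping an already
    analyzed pair (or restarting the watcher) produces no duplicate report.
    """

    def __init__(self, config: QAConfig):
        if not (config.plan_dir and config.log_dir and config.report_dir):
            raise ValueError("watcher needs plan_dir, log_dir and report_dir")
        self.config = config
        self.plan_dir = Path(config.plan_dir)
        self.log_dir = Path(config.log_dir)
        self.report_dir = Path(config.report_dir)
        self.report_dir.mkdir(parents=True, exist_ok=True)
        self._state_path = self.report_dir / "processed.json"
        self._processed: set[str] = set()
        if self._state_path.exists():
            self._processed = set(json.loads(self._state_path.read_text()))
        self._log_first_seen: dict[str, float] = {}
        self._timeout_alerted: set[str] = set()

    def _save_state(self) -> None:
        self._state_path.write_text(json.dumps(sorted(self._processed)))

    def _read_plans(self) -> list[tuple[BeamPlan, Path]]:
        plans = []
        for path in sorted(self.plan_dir.glob("*")):
            if path.suffix.lower() not in (".json", ".dcm"):
                continue
            try:
                if path.suffix.lower() == ".json":
                    plans.append((read_simple_plan(path), path))
                else:
                    plans.extend((p, path) for p in read_rtplan(path))
            except (SchemaError, PlanValidationError, ValueError, OSError) as exc:
                logger.error("unreadable plan %s: %s", path, exc)
                self._alert_problem(f"unreadable plan {path.name}: {exc}")
        return plans

    def _read_logs(self) -> list[tuple[DeliveryLog, Path]]:
        logs = []
        now = time.monotonic()
        for path in sorted(self.log_dir.glob("*.csv")):
            self._log_first_seen.setdefault(str(path), now)
            try:
                lg = read_log(path)
            except (LogParseError, LogValidationError, OSError) as exc:
                logger.error("unreadable log %s: %s", path, exc)
                self._alert_problem(f"unreadable log {path.name}: {exc}")
                continue
            if is_complete(lg, self.config.holdoff_s):
                logs.append((lg, path))
        return logs

    def _alert_problem(self, message: str) -> None:
        if self.config.alert_dir is None:
            return
        alert_dir = Path(self.config.alert_dir)
        alert_dir.mkdir(parents=True, exist_ok=True)
        digest = _sha256_text(message)[:12]
        (alert_dir / f"alert_problem_{digest}.json").write_text(
            json.dumps({"problem": message}, sort_keys=True), encoding="utf-8")

    def poll_once(self) -> list[QAReport]:
        """One scan: analyze every new complete (plan, log) pair; return the
        reports produced in this poll."""
        plans = self._read_plans()
        logs = self._read_logs()
        match = match_plan_log([p for p, _ in plans], [lg for lg, _ in logs])
        for msg in match.ambiguous:
            logger.warning("ambiguous match: %s", msg)
        plan_paths = {id(p): path for p, path in plans}
        log_paths = {id(lg): path for lg, path in logs}

        reports = []
        for plan, lg in match.matched:
            ppath, lpath = plan_paths[id(plan)], log_paths[id(lg)]
            key = f"{_sha256_file(ppath)}:{_sha256_file(lpath)}"
            if key in self._processed:
                continue
            report = analyze(plan, lg, self.config, plan_path=ppath, log_path=lpath)
            rpath = self.report_dir / (
                f"report_{plan.plan_id}_{plan.beam_id}_"
                f"{report.provenance['log_digest'][:12]}.json"
            )
            rpath.write_text(report.to_json(), encoding="utf-8")
            notify(report, self.config.alert_dir, self.config.alert_command, rpath)
            self._processed.add(key)
            reports.append(report)
            logger.info("analyzed %s/%s: %s", plan.plan_id, plan.beam_id, report.verdict)
        if reports:
            self._save_state()

        # logs waiting too long for a plan
        now = time.monotonic()
        matched_logs = {id(lg) for _, lg in match.matched}
        for lg, path in logs:
            if id(lg) in matched_logs:
                continue
            key = str(path)
            waited = now - self._log_first_seen.get(key, now)
            if waited > self.config.pending_timeout_s and key not in self._timeout_alerted:
                self._alert_problem(
                    f"log {path.name} has no matching plan after {waited:.0f} s")
                self._timeout_alerted.add(key)
        return reports


def watch(
    config: QAConfig,
    poll_interval_s: float = 1.0,
    stop_event=None,
    max_polls: int | None = None,
) -> int:
    """Run the watcher loop; returns the number of reports produced.

    Stops cleanly when ``stop_event`` (a ``threading.Event``) is set or after
    ``max_polls`` scans; KeyboardInterrupt also shuts down cleanly.
    """
    watcher = Watcher(config)
    produced = 0
    polls = 0
    try:
        while True:
            produced += len(watcher.poll_once())
            polls += 1
            if max_polls is not None and polls >= max_polls:
                break
            if stop_event is not None and stop_event.wait(poll_interval_s):
                break
            if stop_event is None:
                time.sleep(poll_interval_s)
    except KeyboardInterrupt:
        logger.info("watcher interrupted; shutting down")
    return produced
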