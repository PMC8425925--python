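"""Association between two QA scoring systems via 2x2 contingency analysis.

Each delivered field carries a pair of gamma passing scores: one from the
reference (measurement-style) system and one from the log-file analysis.
Scores are dichotomized at a passing threshold gamma_t -- a score strictly
*above* the threshold is a pass, a tie is a fail -- and counted into a 2x2
table laid out with log-system rows (Pass, Fail) and reference-system
columns (Fail, Pass):

            ref Fail   ref Pass
  log Pass     a          b
  log Fail     c          d

The association statistic phi is *defined* as the Pearson correlation of the
two 0/1 pass vectors (which is layout-free and fixes the sign so phi = +1
means perfect agreement); under the layout above that equals
(b*c - a*d) / sqrt((a+b)(c+d)(a+c)(b+d)).  Significance uses the 1-df
chi-square statistic chi2 = n * phi^2 (no continuity correction, preserving
the identity); Fisher's exact test is available for small counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScorePair",
    "ContingencyTable",
    "SweepEntry",
    "SweepResult",
    "DegenerateTableError",
    "build_table",
    "phi",
    "p_value",
    "threshold_sweep",
    "rank_correlation",
    "read_cohort_csv",
    "write_cohort_csv",
    "make_score_cohort",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (90.0, 92.5, 95.0, 97.5)


class DegenerateTableError(ValueError):
    """A statistic is not computable (zero marginal / constant scores)."""


@dataclass(frozen=True)
class ScorePair:
    """Paired passing scores (percent) for one delivered field."""

    field_id: str
    score_ref_pct: float
    score_log_pct: float
    criteria_label: str = "3%,3mm"

    def __post_init__(self) -> None:
        for s in (self.score_ref_pct, self.score_log_pct):
            if not 0.0 <= s <= 100.0:
                raise ValueError(f"score {s} outside [0, 100]")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows log-system (Pass, Fail), columns reference (Fail, Pass)."""

    a: int  # log pass, ref fail
    b: int  # log pass, ref pass
    c: int  # log fail, ref fail
    d: int  # log fail, ref pass

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def marginals(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def degenerate_reason(self) -> str | None:
        names = ("log-pass row", "log-fail row", "ref-fail column", "ref-pass column")
        for m, name in zip(self.marginals, names):
            if m == 0:
                return f"zero marginal ({name})"
        return None


def build_table(pairs: Sequence[ScorePair], gamma_t_pct: float) -> ContingencyTable:
    """Dichotomize paired scores at ``gamma_t_pct`` (strictly above = pass)."""
    if not pairs:
        raise ValueError("no score pairs")
    a = b = c = d = 0
    for p in pairs:
        log_pass = p.score_log_pct > gamma_t_pct
        ref_pass = p.score_ref_pct > gamma_t_pct
        if log_pass and ref_pass:
            b += 1
        elif log_pass:
            a += 1
        elif ref_pass:
            d += 1
        else:
            c += 1
    return ContingencyTable(a, b, c, d)


def phi(table: ContingencyTable) -> float:
    """Phi coefficient: Pearson correlation of the two 0/1 pass vectors.

    +1 means the two systems agree perfectly on pass/fail, -1 perfect
    disagreement.  Raises :class:`DegenerateTableError` when a marginal is
    zero (the correlation of a constant vector is undefined).
    """
    reason = table.degenerate_reason()
    if reason is not None:
        raise DegenerateTableError(f"phi not computable: {reason}")
    a, b, c, d = table.a, table.b, table.c, table.d
    m1, m2, m3, m4 = table.marginals
    return (b * c - a * d) / math.sqrt(float(m1) * m2 * m3 * m4)


def p_value(table: ContingencyTable, method: str = "chi2") -> float:
    """Two-sided significance of the association.

    ``chi2`` (default): upper tail of chi2 = n * phi^2 with 1 df, no
    continuity correction.  ``fisher``: Fisher's exact test, preferable for
    small counts.
    """
    if method == "chi2":
        ph = phi(table)  # raises on zero marginal
        return float(stats.chi2.sf(table.n * ph * ph, df=1))
    if method == "fisher":
        counts = [[table.b, table.a], [table.d, table.c]]
        return float(stats.fisher_exact(counts).pvalue)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class SweepEntry:
    gamma_t_pct: float
    criteria_label: str
    table: ContingencyTable
    phi: float | None
    p_value: float | None
    not_computable_reason: str | None = None


@dataclass
class SweepResult:
    entries: list[SweepEntry] = field(default_factory=list)

    def entry(self, gamma_t_pct: float, criteria_label: str) -> SweepEntry:
        for e in self.entries:
            if e.gamma_t_pct == gamma_t_pct and e.criteria_label == criteria_label:
                return e
        raise KeyError((gamma_t_pct, criteria_label))

    def phis(self, criteria_label: str) -> list[tuple[float, float | None]]:
        return [(e.gamma_t_pct, e.phi) for e in self.entries
                if e.criteria_label == criteria_label]


def threshold_sweep(
    pairs: Sequence[ScorePair],
    thresholds: Iterable[float] = DEFAULT_THRESHOLDS,
) -> SweepResult:
    """Build a table and compute phi / p at each (threshold, criteria label).

    Pairs are grouped by their ``criteria_label``; combinations whose table
    has a zero marginal are carried as not-computable with a reason rather
    than dropped.
    """
    labels = sorted({p.criteria_label for p in pairs})
    result = SweepResult()
    for label in labels:
        group = [p for p in pairs if p.criteria_label == label]
        for t in thresholds:
            table = build_table(group, t)
            reason = table.degenerate_reason()
            if reason is None:
                result.entries.append(
                    SweepEntry(t, label, table, phi(table), p_value(table))
                )
            else:
                result.entries.append(
                    SweepEntry(t, label, table, None, None, reason)
                )
    return result


def rank_correlation(pairs: Sequence[ScorePair]) -> float:
    """Spearman rank correlation of (reference, log) scores, average ranks
    for ties.  Raises when either system's scores are constant."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    ref = np.array([p.score_ref_pct for p in pairs])
    log = np.array([p.score_log_pct for p in pairs])
    if np.ptp(ref) == 0 or np.ptp(log) == 0:
        raise DegenerateTableError(
            "rank correlation not computable: constant scores in one system")
    rho = stats.spearmanr(ref, log).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# Cohort I/O and synthetic cohort
# ---------------------------------------------------------------------------


def read_cohort_csv(path: str | Path) -> list[ScorePair]:
    """Read paired scores from CSV with columns
    field_id, criteria_label, score_ref_pct, score_log_pct."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"field_id", "criteria_label", "score_ref_pct", "score_log_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns {sorted(missing)}")
    return [
        ScorePair(
            field_id=str(r.field_id),
            score_ref_pct=float(r.score_ref_pct),
            score_log_pct=float(r.score_log_pct),
            criteria_label=str(r.criteria_label),
        )
        for r in df.itertuples(index=False)
    ]


def write_cohort_csv(pairs: Sequence[ScorePair], path: str | Path) -> None:
    pd.DataFrame(
        {
            "field_id": [p.field_id for p in pairs],
            "criteria_label": [p.criteria_label for p in pairs],
            "score_ref_pct": [p.score_ref_pct for p in pairs],
            "score_log_pct": [p.score_log_pct for p in pairs],
        }
    ).to_csv(path, index=False)


def make_score_cohort(
    n_fields: int = 220,
    n_error_fields: int = 30,
    seed: int = 13,
    criteria_label: str = "3%,3mm",
) -> list[ScorePair]:
    """Noisy-correlated synthetic QA cohort.

    Emulates a clinical PSQA score distribution: most deliveries are clean,
    with both systems scoring in the high 90s around a shared per-field
    quality (half-normal below 100) plus independent per-system noise; a
    minority of error fields (e.g. wrong-plan deliveries) score far below
    any clinical threshold on both systems.  Dichotomized at increasing
    gamma_t the shared signal is progressively swamped by the independent
    noise, so the phi association weakens with threshold -- the behaviour a
    threshold sweep is designed to expose.
    """
    if n_error_fields > n_fields:
        raise ValueError("n_error_fields cannot exceed n_fields")
    rng = np.random.default_rng(seed)
    n_good = n_fields - n_error_fields
    pairs: list[ScorePair] = []
    quality = 100.0 - np.abs(rng.normal(0.0, 2.5, n_good))
    for i in range(n_good):
        ref = float(np.clip(quality[i] + rng.normal(0.0, 1.5), 0.0, 100.0))
        log = float(np.clip(quality[i] + rng.normal(0.0, 1.0), 0.0, 100.0))
        pairs.append(ScorePair(f"field{i:04d}", ref, log, criteria_label))
    base = rng.uniform(5.0, 80.0, n_error_fields)
    for j in range(n_error_fields):
        ref = float(np.clip(base[j] + rng.normal(0.0, 4.0), 0.0, 100.0))
        log = float(np.clip(base[j] + rng.normal(0.0, 4.0), 0.0, 100.0))
        pairs.append(ScorePair(f"error{j:04d}", ref, log, criteria_label))
    return pairs
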