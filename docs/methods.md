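# Methods

This note records the model implemented by `logqa`, its assumptions, the
default parameters, and the numerical choices, so results can be interpreted
and reproduced without reading the source.

## Scope and model

`logqa` targets **step-and-shoot MLC deliveries**: a beam is a sequence of
static aperture segments; MU accumulates only while leaves hold position and
the beam is off during leaf travel.  The QA signal is the machine's own
delivery log — time-stamped samples of leaf, diaphragm (jaw), gantry and
collimator positions plus cumulative MU and a beam-on flag — compared
against the DICOM RT Plan (or the equivalent JSON plan).

The comparison is performed in **fluence space**, not dose space.  Each
segment contributes its MU to every grid pixel whose center lies inside the
open aperture (leaf-pair interval intersected with the jaw rectangle).  This
aperture–MU product ignores transmission, penumbra, scatter and output
factors: it is the granularity at which a position/MU log can be checked
against a plan, and millimetre-scale aperture errors map directly onto it.
Absolute dose errors that leave positions and MU intact (e.g. output drift)
are invisible to this channel by construction.

## Machine geometry

* Default MLC: 80 leaf pairs of 7.0 mm width (projected at isocenter),
  leaf travel along x, bank A from the negative side, bank B positive.
* Leaf-pair rows partition the y-axis into half-open intervals
  `[low, high)`, so every y belongs to exactly one pair.
* Park positions default to (130.0, 134.0) mm, required to lie outside the
  maximum x field so parked leaves are always jaw-shielded.

## Delivery simulator

The simulator emulates a listener sampling the machine state at a fixed
rate; it exists so the full pipeline is testable without clinical data.

Defaults (`SimConfig`):

| parameter | default | why |
|---|---|---|
| dose rate | 400/60 MU/s (400 MU/min) | typical clinical step-and-shoot rate |
| sampling rate | 4 Hz | typical machine-log/listener granularity |
| leaf jitter SD | 0.1 mm | well inside the 1 mm leaf tolerance of a healthy machine |
| gantry jitter SD | 0.05° | well inside the 1° gantry tolerance |
| leaf speed | 25 mm/s | finite travel between segments |

Timeline: one beam-off record at t = 0; for each segment,
`ceil(duration/dt)` beam-on samples on the dt grid with the final sample's
cumulative MU clamped exactly to the segment boundary (so the log's total MU
equals the plan's bit-exactly); at least one beam-off travel record between
segments with leaves moving at the configured speed; a 2.5 s beam-off tail
so the streaming completeness hold-off (2 s) is satisfied.  Jitter is
Gaussian truncated at ±3 SD and is applied per sample; identical
(plan, config, errors) produce byte-identical logs.

Injectable errors: `systematic_leaf_offset` (aperture translation of
targeted pairs), `single_leaf_stuck`, `gantry_offset`, and
`park_override` — closed pairs outside the jaw y-opening are driven to the
park positions (130.0/134.0 mm) regardless of the plan-reported closed
position (110.0 mm in the `prostate_like` fixture), reproducing a real MLC
controller behaviour.

What the simulator does **not** emulate: dosimetric output fluctuation,
leaf-speed limit violations during beam-on, time-varying dose rate,
communication dropouts, rotational couch/collimator motion.

## Segment extraction from a log

Beam-on samples are grouped into stationary runs, split where any leaf moves
≥ `stationarity_tol_mm` (default 0.3 mm) between consecutive samples or
where the beam toggles.  Because per-sample jitter can exceed that threshold
without the aperture changing (two ±3 SD excursions of 0.1 mm jitter give
consecutive differences up to 0.6 mm), adjacent runs with **no intervening
sample** are re-merged when their per-leaf mean positions agree within
**twice** the stationarity tolerance — the worst-case separation of two
noisy estimates of the same static aperture under ±3 SD-truncated jitter.
Genuine step-and-shoot segments are always separated by beam-off travel
samples and are therefore never merge candidates.  Segment MU is the
cumulative-MU difference from the record preceding the run to the run's
last record, so no MU is lost to sampling; sub-threshold intervals
(< 0.1 MU by default) are discarded but counted.  Per-segment positions are
the means over the run's samples (circular mean for the gantry), and the
mean short-circuits to the exact sample value when all samples agree, so
zero-noise extraction reproduces the logged positions bit-exactly.

## Fluence grid and rasterization

* Isotropic grid, default 1.0 mm pitch; pixel openness is evaluated at the
  pixel center; leaf rows are half-open in y.
* The automatic grid covers every jaw-clipped open aperture plus a 10 mm
  margin, with the origin snapped to the spacing lattice offset by half a
  pixel so integer field edges fall on pixel boundaries.
* The analysis grid for a plan-vs-log comparison additionally covers the
  *delivered* apertures, so a grossly wrong delivery (wrong plan's log) is
  rasterized and scored low rather than raising a coverage error.
* Jaw-shielded leaf positions (e.g. parked closed pairs) contribute no
  pixels and need no grid coverage.
* The map integral (pixel sum × pixel area) equals the sum over segments of
  MU × pixel-counted open area by construction; this conservation is
  verified against independent pixel counting in the tests.

## Gamma index

For reference pixel r:
`gamma(r) = min_e sqrt(|r−e|² / DTA² + (D_eval(e) − D_ref(r))² / dD²)`.

* Defaults: 3% dose tolerance, 3 mm DTA, **global** normalization
  (dD = 3% of the reference-map maximum, computed as `max × pct / 100` so
  the uniform closed forms are floating-point exact), 10% low-dose
  threshold applied to reference pixels only (excluded from the passing
  denominator).  A per-pixel "local" mode is available.
* A pixel passes when gamma ≤ 1; passing rate = passed / included × 100.
* Production search: the evaluated map is bilinearly upsampled by an
  integer factor giving a step ≤ DTA/10 and searched within a radius of
  3 × DTA via shifted-slice minimization.
* Oracle: `gamma_brute_force` exhaustively scans *every* upsampled node in
  physical coordinates (no radius cap), restricted to ≤ 64-pixel sides.
  Both routes agree exactly whenever the same-position dose difference
  alone gives gamma < 3, because any point beyond 3 × DTA costs at least 3
  from the distance term; the test generators enforce that precondition.

## Positional QA

Per segment, delivered means are compared with the plan: gantry (wrapped to
(−180°, 180°]), four jaw edges, and both banks of every leaf pair.
Default tolerances (TG-142-flavoured): gantry 1.0°, jaws 2.0 mm, leaves
1.0 mm; collimator judged only if a tolerance is supplied; the
`strict` profile tightens the gantry bound to 0.2°.

Leaf pairs are classified **from the planned state only** (the exclusion
rule must not depend on the delivered positions it excuses), with
precedence: `in_field` (pair's y-row intersects the jaw y-opening) →
`guard` (within 1 pair of the outermost intersecting pair) →
`closed_parked` (gap ≤ 0.5 mm, shielded) → `under_diaphragm`.  All but
`in_field` are excluded: their raw deviations are carried in the report but
never affect the verdict.  This is what lets a park override — tens of
millimetres of raw "deviation" on shielded closed leaves — pass cleanly
while remaining visible in the report.  A segment-count mismatch is a
reported failure, not an exception.

## Contingency analysis

Paired per-field scores from two systems are dichotomized at a threshold
γ_t: a score **strictly above** γ_t passes, a tie fails.  The 2×2 table has
log-system rows (Pass, Fail) and reference-system columns (Fail, Pass).
The phi coefficient is *defined* as the Pearson correlation of the two 0/1
pass vectors (layout-free, sign-fixed: +1 = perfect agreement), which under
that layout equals `(bc − ad) / sqrt((a+b)(c+d)(a+c)(b+d))`.  Significance
uses the 1-df chi-square `n·phi²` (no continuity correction, preserving the
identity) or Fisher's exact test for small counts; zero-marginal tables are
reported as not computable with a reason instead of silently dropped.
Spearman rank correlation (average ranks for ties) complements the
dichotomized view.

The synthetic cohort (`make_score_cohort`, default 220 fields / 30 error
fields) models most deliveries as clean — both systems scoring near a
shared per-field quality (100 − |N(0, 2.5)|) plus independent per-system
noise (SD 1.5 and 1.0) — and a minority of error fields scoring far below
any clinical threshold on both systems (U(5, 80) + N(0, 4)).  As γ_t rises,
the shared signal is progressively swamped by the independent noise, so phi
weakens with threshold — the behaviour a threshold sweep is designed to
expose.

## Pipeline

* Matching is exact on (plan_id, beam_id); duplicates are flagged ambiguous
  and never guessed.
* `analyze` is deterministic given inputs and config; wall-clock time is
  isolated in one report field; provenance carries SHA-256 digests of the
  input files (or canonical serializations), the full config and the
  software version.
* Verdict: `fail` iff the gamma pass rate is below the alert threshold
  (default 90%), any positional channel fails, the segment counts mismatch,
  or the plan and log geometries are incompatible; `error` iff a stage is
  undefined for the inputs (e.g. no beam-on samples).  Exit codes: 0 pass,
  1 fail, 2 error.
* The watcher is a polling loop (no OS file-event dependency) keyed on the
  (plan digest, log digest) pair, persisted to `processed.json`, so each
  pair is analyzed exactly once across restarts.  Incomplete logs (beam
  still on, or hold-off not elapsed) wait; unreadable files and logs
  without a plan after a timeout raise problem alerts.  Alert hooks (file
  and optional command) fire only on fail/error; hook failures are logged,
  never raised.

## Limitations

* Fluence is an idealized aperture–MU product on a finite grid; pass rates
  depend on grid pitch near aperture edges (1 mm default; configurable).
* Log positions are trusted as ground truth for the delivery; a mis-
  calibrated encoder is invisible, as in any log-file QA.
* The gamma comparison upsamples only the evaluated map; reference pixels
  are compared at their native centers.
* The simulator's error menu is small and stylized; it demonstrates
  sensitivity, it does not model machine failure statistics.
* The synthetic cohort is a statistical stand-in for clinical score
  distributions, not a clinical dataset.
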