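# logqa

Automated log-file-based patient-specific QA for step-and-shoot MLC
radiotherapy deliveries.

## The problem

In step-and-shoot IMRT a treatment beam is delivered as a sequence of static
multi-leaf-collimator (MLC) apertures, each holding its monitor units (MU)
while the leaves stand still and moving only while the beam is off.
Patient-specific QA traditionally compares a phantom measurement against the
plan before treatment.  A complementary (and automatable) channel is
*log-file QA*: the machine's own delivery log — sampled leaf, jaw and gantry
positions plus cumulative MU — is compared against the plan for every
delivered beam, with no measurement session.

`logqa` implements that channel end to end:

1. **Plan I/O** — DICOM RT Plan (static beams) and a plain-JSON plan format.
2. **Log I/O** — a CSV delivery-log dialect with validation and streaming
   completeness detection (beam-off hold-off).
3. **Delivery simulator** — generates realistic logs from a plan (dose rate,
   sampling rate, leaf jitter, finite leaf speed) with injectable delivery
   errors, so the whole pipeline is testable without clinical data.
4. **Fluence reconstruction** — collapses the log's beam-on samples into
   stationary segments and rasterizes MU-weighted apertures for both plan
   and delivery on a common isocenter-plane grid.
5. **Gamma analysis** — 2D gamma index (default 3%, 3 mm, global
   normalization, 10% low-dose threshold), with an accelerated
   radius-limited search and an exhaustive brute-force oracle for
   verification.
6. **Positional QA** — delivered vs planned gantry/jaw/leaf positions under
   TG-142-style tolerances, with leaf-exclusion rules so that, e.g., an MLC
   controller parking shielded closed leaves far from their plan-reported
   position is recorded but never fails a clean delivery.
7. **Contingency analysis** — association between two QA scoring systems
   (phi coefficient = Pearson correlation of pass vectors, chi-square,
   Fisher, Spearman) swept over passing thresholds.
8. **Pipeline** — plan/log matching, one-shot analysis with verdict and
   provenance, alert hooks, and a polling directory watcher for an
   automated clinical loop.

See `docs/methods.md` for the model, its assumptions, and numerical choices.

## Test

```sh
pip install -e '.[test]'   # adds pytest + hypothesis
python -m pytest -q
```

`tests/test_acceptance.py` holds the end-to-end property suite (oracle
equivalences, closed forms, invariances); the other files are per-module
unit tests.

## Worked example

Create a 7-segment fixture plan, simulate its delivery with realistic
jitter, and analyze the log against the plan:

```sh
$ logqa make-plan --kind prostate_like --pairs 80 --seed 7 -o plan.json
wrote plan.json: 7 segments, 100 MU

$ logqa simulate --plan plan.json --seed 1 -o delivery.csv
wrote delivery.csv: 85 records, 100 MU delivered

$ logqa analyze --plan plan.json --log delivery.csv -o report.json
wrote report.json: verdict pass
```

The report (excerpt) shows a clean delivery: every one of the 5068
above-threshold fluence pixels passes 3%/3 mm gamma, and the worst in-field
leaf deviation is ~0.11 mm, far inside the 1 mm tolerance:

```json
{
  "verdict": "pass",
  "gamma": {
    "criteria": "3%,3mm",
    "pass_rate_pct": 100.0,
    "n_included": 5068,
    "n_passed": 5068,
    "n_delivered_segments": 7
  },
  "positional": {
    "overall_pass": true,
    "max_gantry_dev_deg": 0.0446,
    "max_mlc_dev_mm": 0.1087,
    "max_excluded_mlc_dev_mm": 0.1158
  }
}
```

Injecting a 5 mm systematic in-field leaf offset is caught by both
channels (`logqa analyze` exits 1 on a failing verdict, so it slots into
scripted workflows):

```sh
$ logqa simulate --plan plan.json --seed 1 \
    --error systematic_leaf_offset --error-magnitude 5 -o bad.csv
$ logqa analyze --plan plan.json --log bad.csv -o bad_report.json
wrote bad_report.json: verdict fail
```

```json
{
  "verdict": "fail",
  "reasons": [
    "gamma pass rate 73.7% below alert threshold 90.0%",
    "mlc deviation beyond tolerance"
  ]
}
```

For a continuously running loop, `logqa watch --config config.json` polls a
plan directory and a log directory, analyzes each complete (plan, log) pair
exactly once, and fires an alert hook on any failing or erroring report.

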