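"""2x2 contingency analysis: phi, chi-square identity, sweep, rank correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from logqa import (
    ContingencyTable,
    DegenerateTableError,
    ScorePair,
    build_table,
    make_score_cohort,
    p_value,
    phi,
    rank_correlation,
    read_cohort_csv,
    threshold_sweep,
)
from logqa.contingency import DEFAULT_THRESHOLDS, write_cohort_csv


def _pairs(scores, gamma_t=None, label="3%,3mm"):
    return [ScorePair(f"f{i}", r, l, label) for i, (r, l) in enumerate(scores)]


class TestDichotomization:
    def test_strictly_above_threshold_is_a_pass(self):
        pairs = _pairs([(95.0, 90.0), (90.0, 95.0), (91.0, 91.0), (89.0, 89.0)])
        t = build_table(pairs, 90.0)
        # ties at 90.0 count as fails
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_counts_sum_to_n(self):
        pairs = make_score_cohort(50, 10, seed=3)
        t = build_table(pairs, 95.0)
        assert t.n == 50

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestPhi:
    def test_perfect_agreement_gives_one(self):
        assert phi(ContingencyTable(0, 7, 5, 0)) == 1.0

    def test_no_association_gives_zero(self):
        assert phi(ContingencyTable(5, 5, 5, 5)) == 0.0

    def test_perfect_disagreement_gives_minus_one(self):
        assert phi(ContingencyTable(6, 0, 0, 4)) == -1.0

    def test_zero_marginal_raises_with_reason(self):
        with pytest.raises(DegenerateTableError, match="log-fail row"):
            phi(ContingencyTable(3, 4, 0, 0))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40),
           st.integers(0, 40))
    def test_phi_equals_pearson_of_pass_vectors(self, a, b, c, d):
        """Oracle: phi is by definition the Pearson correlation of the 0/1
        pass indicator vectors the table was counted from."""
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        t = ContingencyTable(a, b, c, d)
        log_v = [1] * (a + b) + [0] * (c + d)
        ref_v = [0] * a + [1] * b + [0] * c + [1] * d
        expected = np.corrcoef(log_v, ref_v)[0, 1]
        assert phi(t) == pytest.approx(expected, abs=1e-12)


class TestSignificance:
    def test_chi2_identity_and_scipy_oracle(self):
        t = ContingencyTable(3, 40, 5, 2)
        ph = phi(t)
        chi2 = t.n * ph * ph
        # identity chi2 = n phi^2 against scipy's uncorrected chi2
        obs = np.array([[t.b, t.a], [t.d, t.c]])
        scipy_chi2 = stats.chi2_contingency(obs, correction=False).statistic
        assert chi2 == pytest.approx(scipy_chi2, abs=1e-12)
        assert p_value(t) == pytest.approx(stats.chi2.sf(scipy_chi2, 1), abs=1e-15)

    def test_fisher_matches_scipy(self):
        t = ContingencyTable(1, 9, 11, 3)
        expected = stats.fisher_exact([[t.b, t.a], [t.d, t.c]]).pvalue
        assert p_value(t, method="fisher") == pytest.approx(expected, abs=1e-15)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            p_value(ContingencyTable(1, 1, 1, 1), method="bootstrap")


class TestSweep:
    def test_default_thresholds_all_reported(self):
        pairs = make_score_cohort(seed=13)
        sweep = threshold_sweep(pairs)
        assert [e.gamma_t_pct for e in sweep.entries] == list(DEFAULT_THRESHOLDS)
        assert all(e.phi is not None for e in sweep.entries)

    def test_association_weakens_as_threshold_rises(self):
        """On the synthetic cohort the shared quality signal is swamped by
        independent per-system noise at high thresholds, so phi is
        non-increasing across 90 / 92.5 / 95 / 97.5."""
        pairs = make_score_cohort(seed=13)
        phis = [e.phi for e in threshold_sweep(pairs).entries]
        assert all(hi >= lo for hi, lo in zip(phis, phis[1:]))
        assert phis[0] > 0.9          # near-perfect agreement at 90%
        assert phis[-1] < phis[0]     # visibly degraded at 97.5%

    def test_degenerate_combinations_carried_with_reason(self):
        pairs = _pairs([(99.0, 99.0), (98.0, 98.0), (97.0, 97.0)])
        sweep = threshold_sweep(pairs, thresholds=(50.0, 99.5))
        lo = sweep.entry(50.0, "3%,3mm")
        hi = sweep.entry(99.5, "3%,3mm")
        assert lo.phi is None and "zero marginal" in lo.not_computable_reason
        assert hi.phi is None and "zero marginal" in hi.not_computable_reason

    def test_groups_by_criteria_label(self):
        pairs = make_score_cohort(40, 8, seed=2, criteria_label="3%,3mm")
        pairs += make_score_cohort(40, 8, seed=4, criteria_label="3%,2mm")
        sweep = threshold_sweep(pairs, thresholds=(90.0,))
        assert sweep.entry(90.0, "3%,3mm").table.n == 40
        assert sweep.entry(90.0, "3%,2mm").table.n == 40


class TestRankCorrelation:
    def test_matches_scipy_spearman(self):
        pairs = make_score_cohort(60, 12, seed=5)
        ref = [p.score_ref_pct for p in pairs]
        log = [p.score_log_pct for p in pairs]
        assert rank_correlation(pairs) == pytest.approx(
            stats.spearmanr(ref, log).statistic, abs=1e-15)

    def test_known_small_example(self):
        pairs = _pairs([(1.0, 2.0), (2.0, 1.0), (3.0, 4.0), (4.0, 3.0)])
        assert rank_correlation(pairs) == pytest.approx(0.6)

    def test_constant_scores_raise(self):
        pairs = _pairs([(90.0, 91.0), (90.0, 95.0), (90.0, 99.0)])
        with pytest.raises(DegenerateTableError, match="constant"):
            rank_correlation(pairs)


class TestCohortIO:
    def test_csv_roundtrip(self, tmp_path):
        pairs = make_score_cohort(25, 5, seed=1)
        path = tmp_path / "cohort.csv"
        write_cohort_csv(pairs, path)
        back = read_cohort_csv(path)
        assert back == pairs

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("field_id,score_ref_pct\nf0,95.0\n")
        with pytest.raises(ValueError, match="score_log_pct"):
            read_cohort_csv(path)

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ScorePair("f0", 101.0, 50.0)

    def test_cohort_generator_is_deterministic(self):
        assert make_score_cohort(seed=21) == make_score_cohort(seed=21)
        assert make_score_cohort(seed=21) != make_score_cohort(seed=22)
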