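"""Differential expression, intersection, scoring and log-rank tests.

Numerical results are checked against independently coded textbook formulas
(Welch's t with Satterthwaite df; the standard two-group log-rank sum) and
against lifelines as an external log-rank oracle.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sarcomir.containers import ClinicalTable, ExpressionMatrix
from sarcomir.diffexpr import (
    compute_de,
    intersect_signatures,
    logrank_by_median_score,
    logrank_statistic,
    signature_score,
)
from sarcomir.exceptions import (
    ConfigurationError,
    DegenerateSplitError,
    EmptySignatureError,
    InsufficientReplicationError,
)
from sarcomir.synth import simulate_clinical_cohort, simulate_mirna_cohorts


def _matrix(values, groups, features=None):
    features = features or [f"f{i}" for i in range(len(values))]
    samples = [f"s{i}" for i in range(len(values[0]))]
    return ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples),
        pd.Series(groups, index=samples),
    )


def welch_oracle(x, y):
    """Textbook Welch two-sample t with Satterthwaite df, two-sided p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1) / n1, y.var(ddof=1) / n2
    t = (x.mean() - y.mean()) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return t, 2 * stats.t.sf(abs(t), df)


class TestComputeDE:
    def test_welch_matches_textbook_formula(self):
        case_vals = [5.1, 7.3, 6.2]
        ctrl_vals = [4.0, 4.4, 3.1]
        mat = _matrix([case_vals + ctrl_vals], ["case"] * 3 + ["control"] * 3)
        sig = compute_de(mat)
        _, p_expected = welch_oracle(case_vals, ctrl_vals)
        assert sig.table["p"].iloc[0] == pytest.approx(p_expected, rel=1e-10)
        assert sig.table["log2fc"].iloc[0] == pytest.approx(
            np.mean(case_vals) - np.mean(ctrl_vals))

    def test_identical_group_means_unchanged(self):
        mat = _matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], ["case"] * 3 + ["control"] * 3)
        sig = compute_de(mat)
        assert sig.table["log2fc"].iloc[0] == 0
        assert sig.table["direction"].iloc[0] == "unchanged"

    def test_zero_noise_cohort_fully_called(self, zero_noise_cfg):
        cfg = dataclasses.replace(zero_noise_cfg, effect_log2fc=2.0)
        cell, _, truth = simulate_mirna_cohorts(cfg)
        sig = compute_de(cell)
        implanted_down = truth.conserved_down_mirnas | truth.cellline_only_down_mirnas
        assert sig.down == implanted_down
        assert sig.up == truth.up_mirnas
        called = sig.table.loc[sorted(implanted_down | truth.up_mirnas)]
        assert np.allclose(called["log2fc"].abs(), 2.0)

    def test_insufficient_replication_raises(self):
        mat = _matrix([[1.0, 2.0, 3.0]], ["case", "control", "control"])
        with pytest.raises(InsufficientReplicationError):
            compute_de(mat)

    def test_bh_is_permutation_invariant(self, small_world):
        sig = compute_de(small_world["cell"])
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(sig.table))
        mat = small_world["cell"]
        shuffled = ExpressionMatrix(mat.values.iloc[perm], mat.group)
        sig_shuffled = compute_de(shuffled)
        pd.testing.assert_series_equal(
            sig.table["q"].sort_index(), sig_shuffled.table["q"].sort_index())


class TestIntersect:
    def _sig(self, down=(), up=()):
        names = list(down) + list(up)
        table = pd.DataFrame({
            "log2fc": [-2.0] * len(down) + [2.0] * len(up),
            "p": 0.001, "q": 0.01,
            "direction": ["down"] * len(down) + ["up"] * len(up),
        }, index=names)
        from sarcomir.containers import DESignature
        return DESignature(table)

    def test_identity(self):
        sig = self._sig(down=["a", "b"], up=["c"])
        down, up, disc = intersect_signatures(sig, sig)
        assert down == {"a", "b"} and up == {"c"} and disc == set()

    def test_disjoint_lists_empty(self):
        a = self._sig(down=["a"], up=["b"])
        b = self._sig(down=["x"], up=["y"])
        assert intersect_signatures(a, b) == (set(), set(), set())

    def test_symmetry_and_discordance(self):
        a = self._sig(down=["a", "d"], up=["c"])
        b = self._sig(down=["c"], up=["a"])
        down_ab, up_ab, disc_ab = intersect_signatures(a, b)
        down_ba, up_ba, disc_ba = intersect_signatures(b, a)
        assert (down_ab, up_ab, disc_ab) == (down_ba, up_ba, disc_ba)
        assert disc_ab == {"a", "c"} and down_ab == set() and up_ab == set()

    def test_sets_are_disjoint(self, small_world):
        sig_cell = compute_de(small_world["cell"])
        sig_tumor = compute_de(small_world["tumor"])
        down, up, disc = intersect_signatures(sig_cell, sig_tumor)
        assert not (down & up or down & disc or up & disc)


class TestSignatureScore:
    def test_single_feature_equals_zscore(self):
        mat = _matrix([[1.0, 2.0, 3.0, 4.0]], ["case"] * 4)
        score = signature_score(mat, ["f0"])
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        z = (vals - vals.mean()) / vals.std()
        assert np.allclose(score.to_numpy(), z)

    def test_zero_variance_contributes_zero(self):
        mat = _matrix([[5.0, 5.0, 5.0, 5.0]], ["case"] * 4)
        score = signature_score(mat, ["f0"])
        assert (score == 0).all()

    def test_matches_hand_computed_zmeans(self):
        values = [[1.0, 3.0, 5.0, 7.0],
                  [2.0, 2.0, 4.0, 4.0],
                  [0.0, 1.0, 0.0, 1.0]]
        mat = _matrix(values, ["case"] * 4)
        score = signature_score(mat, ["f0", "f1", "f2"])
        expected = np.mean([
            (np.array(row) - np.mean(row)) / np.std(row) for row in values
        ], axis=0)
        assert np.allclose(score.to_numpy(), expected)

    def test_missing_features_skipped_all_missing_raises(self):
        mat = _matrix([[1.0, 2.0]], ["case"] * 2)
        with pytest.raises(EmptySignatureError):
            signature_score(mat, ["nope"])
        score = signature_score(mat, ["f0", "nope"])
        assert len(score) == 2


def _clin(times, events, mets=None):
    mets = mets if mets is not None else [0] * len(times)
    return ClinicalTable(pd.DataFrame(
        {"time_months": times, "event": events, "metastasis": mets},
        index=[f"s{i}" for i in range(len(times))]))


class TestLogrank:
    def test_identical_groups_null(self):
        times = [3.0, 5.0, 8.0, 3.0, 5.0, 8.0]
        events = [1, 1, 0, 1, 1, 0]
        chi2, p = logrank_statistic(times, events, [True, True, True, False, False, False])
        assert chi2 == pytest.approx(0.0, abs=1e-15)
        assert p == pytest.approx(1.0)

    def test_six_sample_example_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        times = [2.0, 4.0, 6.0, 5.0, 7.0, 11.0]
        events = [1, 1, 0, 1, 1, 1]
        group = [True, True, True, False, False, False]
        chi2, p = logrank_statistic(times, events, group)
        res = logrank_test(
            np.array(times)[group], np.array(times)[~np.array(group)],
            np.array(events)[group], np.array(events)[~np.array(group)])
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-10)
        assert p == pytest.approx(res.p_value, rel=1e-10)

    def test_group_relabelling_invariance(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, size=20)
        events = rng.integers(0, 2, size=20)
        events[0] = 1
        group = rng.random(20) < 0.5
        a = logrank_statistic(times, events, group)
        b = logrank_statistic(times, events, ~group)
        assert a == pytest.approx(b)

    def test_median_split_ties_to_low_group(self):
        scores = pd.Series([1.0, 1.0, 2.0, 3.0], index=["s0", "s1", "s2", "s3"])
        clin = _clin([5.0, 6.0, 7.0, 8.0], [1, 1, 1, 1])
        _, _, sizes = logrank_by_median_score(scores, clin)
        # median is 1.5; ties below go low
        assert sizes == {"low": 2, "high": 2}
        scores2 = pd.Series([2.0, 2.0, 2.0, 3.0], index=scores.index)
        _, _, sizes2 = logrank_by_median_score(scores2, clin)
        assert sizes2 == {"low": 3, "high": 1}

    def test_degenerate_split_raises(self):
        scores = pd.Series([1.0, 1.0, 1.0], index=["s0", "s1", "s2"])
        clin = _clin([5.0, 6.0, 7.0], [1, 1, 1])
        with pytest.raises(DegenerateSplitError):
            logrank_by_median_score(scores, clin)

    def test_requires_an_event(self):
        scores = pd.Series([1.0, 2.0], index=["s0", "s1"])
        with pytest.raises(ConfigurationError):
            logrank_by_median_score(scores, _clin([5.0, 6.0], [0, 0]))

    def test_hub_signature_stratifies_survival(self, small_world):
        """Low conserved-miRNA signature score marks the hub-high, short-
        survival subgroup, so a median split separates survival."""
        cohort, truth = small_world["cohort"], small_world["truth"]
        scores = signature_score(cohort.mirna_expr, truth.conserved_down_mirnas)
        chi2, p, sizes = logrank_by_median_score(scores, cohort.clinical)
        assert p < 0.05
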