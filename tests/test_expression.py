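"""qPCR analytics: geNorm M, 2^-ddCq, response classification, correlation."""

import numpy as np
import pandas as pd
import pytest

from mlncforge.expression import (
    classify_cold,
    classify_dehydration,
    correlate_pair,
    cq_matrix,
    delta_delta_cq,
    genorm_m,
    read_cq,
)

SAMPLES = ["t0", "t1", "t5", "t10", "t24"]


def _cq(rows):
    return pd.DataFrame(rows, index=SAMPLES).T


class TestGenorm:
    def test_constant_offset_pair_has_zero_m(self):
        cq = _cq({"g1": [20, 21, 22, 23, 24], "g2": [25, 26, 27, 28, 29]})
        m = genorm_m(cq)
        assert m["g1"] == pytest.approx(0.0, abs=1e-12)
        assert m["g2"] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_gene_largest_m(self):
        rng = np.random.default_rng(0)
        base = np.array([20.0, 21, 22, 23, 24])
        noise = rng.normal(0, 1.0, 5)
        cq = _cq({"g1": base, "g2": base + 3, "g3": base + noise})
        m = genorm_m(cq)
        assert m.idxmax() == "g3"
        # direct recomputation of pairwise SDs
        def v(a, b):
            return float(np.std((cq.loc[a] - cq.loc[b]), ddof=1))
        assert m["g3"] == pytest.approx((v("g3", "g1") + v("g3", "g2")) / 2)

    def test_per_gene_constant_invariance(self):
        rng = np.random.default_rng(1)
        cq = _cq({"g1": rng.normal(20, 1, 5), "g2": rng.normal(24, 1, 5)})
        shifted = cq.copy()
        shifted.loc["g1"] += 7.5
        pd.testing.assert_series_equal(genorm_m(cq), genorm_m(shifted))

    def test_undetected_candidate_excluded(self, caplog):
        cq = _cq({"g1": [20, 21, 22, 23, 24], "g2": [25, 26, 27, 28, 29],
                  "g3": [30, np.nan, 31, 32, 33]})
        with caplog.at_level("WARNING"):
            m = genorm_m(cq)
        assert "g3" not in m.index and len(m) == 2


class TestDeltaDeltaCq:
    def test_identity_and_doubling(self):
        cq = _cq({"ref": [20, 20, 20, 20, 20], "g": [25, 25, 24, 25, 25]})
        fold = delta_delta_cq(cq, "g", "ref", "t0")
        assert fold["t0"] == pytest.approx(1.0)
        assert fold["t5"] == pytest.approx(2.0)  # ddCq = -1

    def test_formula_oracle_random_matrix(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(4)]
        cq = pd.DataFrame(rng.uniform(18, 32, (4, 6)), index=genes,
                          columns=[f"s{j}" for j in range(6)])
        fold = delta_delta_cq(cq, "g1", "g0", "s0")
        for s in cq.columns:
            d = (cq.loc["g1", s] - cq.loc["g0", s]) - (cq.loc["g1", "s0"] - cq.loc["g0", "s0"])
            assert fold[s] == pytest.approx(2.0 ** (-d), rel=1e-12)

    def test_plate_shift_invariance(self):
        rng = np.random.default_rng(3)
        cq = pd.DataFrame(rng.uniform(18, 30, (3, 5)),
                          index=["ref", "a", "b"], columns=SAMPLES)
        shifted = cq + rng.uniform(-2, 2, 5)  # per-sample constant
        f1 = delta_delta_cq(cq, "a", "ref", "t0")
        f2 = delta_delta_cq(shifted, "a", "ref", "t0")
        pd.testing.assert_series_equal(f1, f2)

    def test_undetected_target_is_nan_not_zero(self):
        cq = _cq({"ref": [20] * 5, "g": [25, np.nan, 24, 25, 25]})
        fold = delta_delta_cq(cq, "g", "ref", "t0")
        assert np.isnan(fold["t1"]) and fold["t1"] != 0


def _series(values):
    return pd.Series(dict(zip([0, 1, 5, 10, 24], values)))


class TestResponseClassifiers:
    @pytest.mark.parametrize(
        "values,subclass,responsive",
        [
            ((1, 1.3, 0.8, 1.1, 0.9), "A", False),
            ((1, 0.4, 0.3, 0.3, 0.6), "B", True),
            ((1, 5, 2, 0.5, 0.3), "C", True),
            ((1, 1.2, 4.0, 2.0, 0.6), "C", True),  # peak at 5 h
            ((1, 0.9, 1.1, 1.0, 3.0), "unclassified", True),  # late rise: no cold rule
        ],
    )
    def test_cold(self, values, subclass, responsive):
        rc = classify_cold("g", _series(values))
        assert (rc.subclass, rc.responsive) == (subclass, responsive)

    @pytest.mark.parametrize(
        "values,subclass",
        [
            ((1, 1.1, 0.9, 1.2, 2.5), "I"),
            ((1, 0.3, 0.25, 0.3, 0.4), "II"),
            ((1, 3.2, 0.8, 0.4, 0.3), "III"),
        ],
    )
    def test_dehydration(self, values, subclass):
        rc = classify_dehydration("g", _series(values))
        assert rc.subclass == subclass and rc.responsive

    def test_missing_time_point_refused(self):
        with pytest.raises(ValueError):
            classify_cold("g", pd.Series({0: 1.0, 1: 2.0, 5: 1.0}))

    def test_subclasses_mutually_exclusive_rule_order(self):
        # drops below 1/2 at 1 h AND rebounds >= 2-fold: B wins over C
        rc = classify_cold("g", _series((1, 0.4, 3.0, 1.0, 0.5)))
        assert rc.subclass == "B"


class TestCorrelation:
    def test_proportional_series_positive(self):
        a = _series((1, 2, 4, 2, 1))
        b = 2 * a
        sign, r = correlate_pair(a, b)
        assert sign == "positive" and r == pytest.approx(1.0)

    def test_reciprocal_series_negative(self):
        a = _series((1, 2, 4, 2, 1))
        sign, r = correlate_pair(a, 1 / a)
        assert sign == "negative" and r == pytest.approx(-1.0)

    def test_zero_variance_none(self):
        sign, r = correlate_pair(_series((1, 1, 1, 1, 1)), _series((1, 2, 3, 4, 5)))
        assert sign == "none" and np.isnan(r)

    def test_subset_of_time_points(self):
        a = _series((1, 9, 2, 4, 8))
        b = _series((1, 0.1, 2.1, 4.2, 7.9))
        sign_late, _ = correlate_pair(a, b, time_points=[5, 10, 24])
        assert sign_late == "positive"

    def test_independent_series_mean_r_near_zero(self):
        rng = np.random.default_rng(4)
        rs = []
        for _ in range(1000):
            a = pd.Series(2.0 ** rng.normal(0, 1, 5), index=[0, 1, 5, 10, 24])
            b = pd.Series(2.0 ** rng.normal(0, 1, 5), index=[0, 1, 5, 10, 24])
            _, r = correlate_pair(a, b, threshold=0.0)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05  # Monte-Carlo error at n=1000


def test_read_cq_marks_undetected(tmp_path):
    p = tmp_path / "cq.tsv"
    p.write_text("gene\tsample\treplicate\tcq\ng1\tt0\t1\t20.0\ng1\tt1\t1\t40.0\n")
    df = read_cq(p)
    mat = cq_matrix(df)
    assert np.isnan(mat.loc["g1", "t1"]) and mat.loc["g1", "t0"] == 20.0
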