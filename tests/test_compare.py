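"""Agreement statistics: MRPAD, paired t, Pearson r, Type III GLM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import icvkit as ik


class TestMrpad:
    def test_zero_when_equal(self):
        assert ik.mrpad([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        assert ik.mrpad([1.1, 1.8], [1.0, 2.0]) == pytest.approx(10.0, abs=1e-12)

    def test_uniform_doubling(self):
        ref = np.array([1.0, 1.3, 1.7])
        assert ik.mrpad(2 * ref, ref) == pytest.approx(100.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(1.0, 2.0, 10)
        est = ref * rng.uniform(0.9, 1.1, 10)
        for c in (0.5, 3.0):
            assert ik.mrpad(c * est, c * ref) == pytest.approx(
                ik.mrpad(est, ref), rel=1e-12
            )

    def test_errors(self):
        with pytest.raises(ValueError):
            ik.mrpad([1.0], [0.0])
        with pytest.raises(ValueError):
            ik.mrpad([1.0, 2.0], [1.0])


class TestPairedT:
    def test_identical_samples(self):
        t, p, df = ik.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p, df) == (0.0, 1.0, 2)

    def test_hand_example(self):
        t, p, df = ik.paired_t_test([1, 2, 4], [2, 3, 4])
        assert t == pytest.approx(-2.0, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(0.1835, abs=2e-4)

    def test_against_scipy(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=12), rng.normal(size=12)
        t, p, _ = ik.paired_t_test(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_p_decreases_with_n_under_constant_shift(self):
        rng = np.random.default_rng(1)
        pvals = []
        for n in (5, 20, 80):
            a = rng.normal(size=n)
            pvals.append(ik.paired_t_test(a, a + 0.5 + rng.normal(0, 0.2, n))[1])
        assert pvals[0] > pvals[2]

    def test_degenerate_nonzero_shift_flagged(self):
        t, p, df = ik.paired_t_test([2.0, 3.0], [1.0, 2.0])
        assert np.isinf(t) and np.isnan(p)

    def test_too_small(self):
        with pytest.raises(ValueError):
            ik.paired_t_test([1.0], [2.0])


class TestPearson:
    def test_perfect_and_anti(self):
        a = np.array([1.0, 2.0, 3.0])
        assert ik.pearson_r(a, a) == pytest.approx(1.0, abs=1e-12)
        assert ik.pearson_r(a, -a) == pytest.approx(-1.0, abs=1e-12)
        assert abs(ik.pearson_r(a, a)) <= 1.0

    def test_hand_example(self):
        assert ik.pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ik.pearson_r([1.0, 1.0], [1.0, 2.0])


def hand_type3_f(y, blocks, term):
    """Nested-model RSS oracle: partial F for one term's column block."""
    full = np.column_stack([np.ones(len(y))] + [blocks[k] for k in blocks])
    reduced = np.column_stack(
        [np.ones(len(y))] + [blocks[k] for k in blocks if k != term]
    )
    rss = lambda X: np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
    df_term = blocks[term].shape[1]
    df_resid = len(y) - full.shape[1]
    return ((rss(reduced) - rss(full)) / df_term) / (rss(full) / df_resid)


def sum_code(labels):
    """Hand-rolled sum-to-zero coding: levels sorted, last level = -1."""
    levels = sorted(set(labels))
    cols = []
    for lev in levels[:-1]:
        col = np.where(np.asarray(labels) == lev, 1.0, 0.0)
        col[np.asarray(labels) == levels[-1]] = -1.0
        cols.append(col)
    return np.column_stack(cols)


class TestFactorialGlm:
    def _random_table(self, rng, n_per_cell=3):
        rows = []
        sid = 0
        for g in ("AD", "AC"):
            for sex in ("F", "M"):
                for _ in range(n_per_cell):
                    age = float(rng.normal(75, 8))
                    for meth in ("manual", "fs", "spm"):
                        rows.append(
                            dict(subject_id=f"s{sid}", group=g, sex=sex, age=age,
                                 method=meth, phase=1,
                                 icv_l=float(rng.normal(1.45, 0.1)))
                        )
                    sid += 1
        return pd.DataFrame(rows)

    def test_one_factor_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(1.4, 0.1, 10), rng.normal(1.5, 0.1, 10)
        df = pd.DataFrame({"icv_l": np.r_[a, b], "method": ["m1"] * 10 + ["m2"] * 10})
        an = ik.type3_anova(df, "icv_l", {"Method": "C(method, Sum)"}, [("Method",)])
        t, p = stats.ttest_ind(a, b)
        assert an.loc["Method", "F"] == pytest.approx(t**2, rel=1e-10)
        assert an.loc["Method", "p"] == pytest.approx(p, rel=1e-10)

    def test_null_factor_f_zero_in_noiseless_balanced_design(self):
        # 2x2 with cell means depending only on the first factor
        rows = []
        for i, g in enumerate(("AD", "AC")):
            for s in ("F", "M"):
                for r in range(3):
                    rows.append(dict(icv_l=1.0 + 0.2 * i + 0.001 * r, group=g, sex=s,
                                     rep=r))
        df = pd.DataFrame(rows)
        an = ik.type3_anova(
            df, "icv_l",
            {"Group": "C(group, Sum)", "Sex": "C(sex, Sum)"},
            [("Group",), ("Sex",), ("Group", "Sex")],
        )
        assert an.loc["Sex", "F"] == pytest.approx(0.0, abs=1e-8)
        assert an.loc["Group:Sex", "F"] == pytest.approx(0.0, abs=1e-8)

    def test_matches_nested_rss_oracle(self):
        """Type III F per term equals the hand design-matrix partial F."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            df = self._random_table(rng)
            an = ik.factorial_glm_anova(df, max_order=2)
            age_c = df["age"] - df["age"].mean()
            g = sum_code(df["group"])
            s = sum_code(df["sex"])
            m = sum_code(df["method"])
            a = age_c.to_numpy()[:, None]
            inter = lambda u, v: np.column_stack(
                [u[:, i] * v[:, j] for i in range(u.shape[1]) for j in range(v.shape[1])]
            )
            blocks = {
                "Group": g, "Sex": s, "Age": a, "Method": m,
                "Group:Sex": inter(g, s), "Group:Age": inter(g, a),
                "Sex:Age": inter(s, a), "Group:Method": inter(g, m),
                "Sex:Method": inter(s, m), "Age:Method": inter(a, m),
            }
            y = df["icv_l"].to_numpy()
            for term in blocks:
                assert an.loc[term, "F"] == pytest.approx(
                    hand_type3_f(y, blocks, term), rel=1e-8
                ), term

    def test_rank_deficient_names_term(self):
        rng = np.random.default_rng(0)
        df = self._random_table(rng, n_per_cell=1)
        df["age"] = 75.0  # constant age aliases the intercept
        with pytest.raises(ValueError, match="age"):
            ik.factorial_glm_anova(df, max_order=2)

    def test_p_values_in_range(self):
        rng = np.random.default_rng(5)
        an = ik.factorial_glm_anova(self._random_table(rng), max_order=3)
        assert ((an["p"] >= 0) & (an["p"] <= 1)).all()
        assert (an["F"] >= 0).all()


def _icv_table(rng, n=8, tools=("fs_like",)):
    rows = []
    for g in ("AD", "AC"):
        for i in range(n):
            sid = f"{g}{i}"
            true = float(rng.normal(1.45, 0.12))
            base = dict(subject_id=sid, group=g, sex="F" if i % 2 else "M",
                        age=float(rng.normal(75, 7)))
            for phase in (1, 2):
                rows.append({**base, "method": "manual_op1", "phase": phase,
                             "icv_l": true * (1 + rng.normal(0, 1e-4))})
            rows.append({**base, "method": "manual_op2", "phase": 1,
                         "icv_l": true * (1 + rng.normal(0, 1e-4))})
            for tool in tools:
                preset = ik.TOOL_PRESETS[tool]
                for phase in (1, 2):
                    rows.append({**base, "method": tool, "phase": phase,
                                 "icv_l": true * preset.mult_bias
                                 * (1 + rng.normal(0, preset.noise_cv))})
    return pd.DataFrame(rows)


class TestBatteries:
    def test_identical_method_perfect_agreement(self):
        rng = np.random.default_rng(2)
        df = _icv_table(rng)
        clone = df[(df.method == "manual_op1") & (df.phase == 1)].copy()
        clone["method"] = "clone"
        res = ik.comparison_battery(
            pd.concat([df, clone], ignore_index=True), group="AD"
        )
        row = next(r for r in res if r.method_a == "clone")
        assert row.t_stat == 0.0 and row.p_value == 1.0
        assert row.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert row.mrpad_percent == 0.0

    def test_biased_tool_detected(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(11):
            true = float(rng.normal(1.45, 0.12))
            base = dict(subject_id=f"AD{i}", group="AD", sex="F", age=80.0)
            rows.append({**base, "method": "manual_op1", "phase": 1, "icv_l": true})
            rows.append({**base, "method": "fsl_like", "phase": 1, "icv_l": 2.77 * true})
        res = ik.comparison_battery(pd.DataFrame(rows), group="AD")
        row = res[0]
        assert row.mrpad_percent == pytest.approx(177.0, abs=1e-9)
        assert row.p_value < 0.01
        assert row.n == 11

    def test_intra_method_noise_contract(self):
        rng = np.random.default_rng(6)
        df = _icv_table(rng, tools=("spm_like",))
        res = ik.intra_method_battery(df, group="AC")
        spm = next(r for r in res if r.method_a.startswith("spm_like"))
        assert spm.mrpad_percent > 0
        assert spm.pearson_r < 1.0

    def test_missing_pairs_reported(self):
        rng = np.random.default_rng(3)
        df = _icv_table(rng)
        df = df.drop(df[(df.subject_id == "AD0") & (df.method == "fs_like")].index)
        with pytest.raises(ValueError, match="AD0"):
            ik.comparison_battery(df, group="AD")

    def test_table_validation(self):
        df = pd.DataFrame(
            [
                dict(subject_id="a", group="AD", sex="F", age=70, method="m",
                     phase=1, icv_l=1.2),
                dict(subject_id="a", group="AD", sex="F", age=70, method="m",
                     phase=1, icv_l=1.3),
            ]
        )
        with pytest.raises(ValueError, match="duplicate"):
            ik.validate_icv_table(df)
        with pytest.raises(ValueError, match="icv_l"):
            ik.validate_icv_table(df.iloc[:1].assign(icv_l=-1.0))
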