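"""QC gates, TPM, expression filter, TMM factors, inverse normal transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from noninvrna.normalize import (
    compute_tpm,
    expression_filter,
    inverse_normal_transform,
    tmm_factors,
)
from noninvrna.qc import DEPTH_PRESETS, coding_depth, prep_qc_gate, seq_qc_gate


class TestPrepQcGate:
    @pytest.mark.parametrize(
        "conc,size,passes,reason",
        [
            (2.5, 400.0, True, ""),
            (1.9, 400.0, False, "LOW_YIELD"),
            (2.5, 650.0, False, "OVERSIZE"),
            (1.9, 650.0, False, "LOW_YIELD,OVERSIZE"),
            (2.0, 400.0, False, "LOW_YIELD"),  # boundary: must exceed 2 nM
            (2.5, 600.0, False, "OVERSIZE"),  # boundary: must be under 600 bp
        ],
    )
    def test_gate_decisions(self, conc, size, passes, reason):
        samples = pd.DataFrame({"lib_concentration": [conc], "lib_size": [size]}, index=["s"])
        out = prep_qc_gate(samples)
        assert out.loc["s", "pass_qc"] == passes
        assert out.loc["s", "reasons"] == reason

    def test_missing_fields_flagged_not_passed(self):
        samples = pd.DataFrame(
            {"lib_concentration": [np.nan], "lib_size": [400.0]}, index=["s"]
        )
        out = prep_qc_gate(samples)
        assert not out.loc["s", "pass_qc"]
        assert out.loc["s", "reasons"] == "UNEVALUABLE"


class TestCodingDepth:
    def test_mixed_biotypes_hand_sum(self, toy_counts):
        counts, annot = toy_counts
        depth = coding_depth(counts, annot)
        assert depth["s1"] == 5 + 3  # protein_coding + lncRNA, not "other"

    def test_all_other_gives_zero(self, toy_counts):
        counts, annot = toy_counts
        annot = annot.assign(biotype="other")
        assert (coding_depth(counts, annot) == 0).all()

    def test_unannotated_gene_rejected(self, toy_counts):
        counts, annot = toy_counts
        with pytest.raises(KeyError):
            coding_depth(counts, annot.iloc[:2])


class TestSeqQcGate:
    def test_boundary_inclusive(self):
        depths = pd.Series({"a": 1e6, "b": 999_999.0})
        out = seq_qc_gate(depths, 1e6)
        assert out["a"] and not out["b"]

    @pytest.mark.parametrize(
        "preset,value", [("cross-prep", 1e6), ("loseq", 2.5e6), ("gtex", 5e6)]
    )
    def test_presets(self, preset, value):
        assert DEPTH_PRESETS[preset] == value
        depths = pd.Series({"a": value, "b": value - 1})
        out = seq_qc_gate(depths, preset)
        assert out["a"] and not out["b"]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            seq_qc_gate(pd.Series({"a": 1.0}), -5)


class TestTpm:
    def test_single_expressed_gene_takes_all(self):
        counts = pd.DataFrame({"s": [10, 0]}, index=["g1", "g2"])
        tpm = compute_tpm(counts, pd.Series({"g1": 100, "g2": 100}))
        assert tpm.loc["g1", "s"] == 1e6

    def test_length_normalization_closed_form(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["g1", "g2"])
        tpm = compute_tpm(counts, pd.Series({"g1": 1000, "g2": 2000}))
        assert tpm["s"].to_numpy() == pytest.approx([2e6 / 3, 1e6 / 3])

    def test_depth_scale_invariance_and_conservation(self, small_sim):
        lengths = small_sim.genes["length"]
        t1 = compute_tpm(small_sim.counts, lengths)
        t2 = compute_tpm(small_sim.counts * 2, lengths)
        assert np.allclose(t1, t2)
        assert np.allclose(t1.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_depth_sample_warns_not_nan(self):
        counts = pd.DataFrame({"s": [0, 0]}, index=["g1", "g2"])
        with pytest.warns(UserWarning):
            tpm = compute_tpm(counts, pd.Series({"g1": 100, "g2": 100}))
        assert (tpm["s"] == 0).all()


class TestExpressionFilter:
    def _toy(self):
        # 10 samples; g1 passes jointly in exactly 2/10, g2 fails TPM,
        # g3 passes everywhere, g4 passes counts in 1/10 only
        counts = pd.DataFrame(
            [[8, 8] + [0] * 8, [100] * 10, [50] * 10, [9] + [0] * 9],
            index=["g1", "g2", "g3", "g4"],
            columns=[f"s{i}" for i in range(10)],
        )
        tpm = pd.DataFrame(
            [[0.1, 0.1] + [0.0] * 8, [0.05] * 10, [5.0] * 10, [1.0] + [0.0] * 9],
            index=counts.index,
            columns=counts.columns,
        )
        return counts, tpm

    def test_boundary_and_joint_condition(self):
        counts, tpm = self._toy()
        kept = expression_filter(counts, tpm)
        assert list(kept) == ["g1", "g3"]  # g1 at exact 20%/count 8/TPM 0.1 boundary

    def test_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 20, size=(30, 10)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(10)],
        )
        tpm = pd.DataFrame(
            rng.uniform(0, 0.3, size=(30, 10)), index=counts.index, columns=counts.columns
        )
        kept = set(expression_filter(counts, tpm, min_count=8, min_tpm=0.1, min_frac=0.2))
        expected = {
            g
            for g in counts.index
            if sum(
                (counts.loc[g, s] >= 8) and (tpm.loc[g, s] >= 0.1) for s in counts.columns
            )
            >= 2
        }
        assert kept == expected

    def test_monotone_in_thresholds(self):
        counts, tpm = self._toy()
        strict = set(expression_filter(counts, tpm, min_count=8, min_tpm=0.1, min_frac=0.2))
        for kw in ({"min_count": 5}, {"min_tpm": 0.01}, {"min_frac": 0.1}):
            relaxed = set(expression_filter(counts, tpm, **{"min_count": 8, "min_tpm": 0.1, "min_frac": 0.2, **kw}))
            assert strict <= relaxed

    def test_empty_sample_set_rejected(self):
        counts, tpm = self._toy()
        with pytest.raises(ValueError):
            expression_filter(counts.iloc[:, :0], tpm.iloc[:, :0])


def _tmm_oracle(obs, ref, trim_m=0.30, trim_a=0.05):
    """Brute-force doubly trimmed weighted mean of raw-count log-ratios."""
    n_o, n_r = obs.sum(), ref.sum()
    use = (obs > 0) & (ref > 0)
    o, r = obs[use].astype(float), ref[use].astype(float)
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = 1.0 / ((n_o - o) / (n_o * o) + (n_r - r) / (n_r * r))
    n = len(m)
    m_ord = stats.rankdata(m, method="ordinal")
    a_ord = stats.rankdata(a, method="ordinal")
    keep = np.array(
        [
            (m_ord[i] > n * trim_m)
            and (m_ord[i] <= n * (1 - trim_m))
            and (a_ord[i] > n * trim_a)
            and (a_ord[i] <= n * (1 - trim_a))
            for i in range(n)
        ]
    )
    return 2 ** (np.sum(m[keep] * w[keep]) / np.sum(w[keep]))


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 101)
        counts = pd.DataFrame({"a": col, "b": col, "c": col})
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0)

    def test_doubled_column_recovered(self, small_sim):
        counts = small_sim.counts.iloc[:, :3].copy()
        counts["doubled"] = counts.iloc[:, 0] * 2
        f = tmm_factors(counts)
        assert f["doubled"] / f[counts.columns[0]] == pytest.approx(2.0, rel=0.01)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(40, 2)), columns=["ref", "obs"]
        )
        f = tmm_factors(counts, ref_sample="ref")
        oracle = _tmm_oracle(counts["obs"].to_numpy(), counts["ref"].to_numpy())
        ratio_impl = f["obs"] / f["ref"]
        assert ratio_impl == pytest.approx(oracle, rel=1e-10)

    def test_geometric_mean_one_and_rescale_invariance(self, small_sim):
        counts = small_sim.counts.iloc[:, :5]
        f1 = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f1))) == pytest.approx(1.0, abs=1e-10)
        f2 = tmm_factors(counts * 3)
        assert np.allclose(f1, f2)

    def test_too_few_usable_genes_warns_unit_factor(self):
        counts = pd.DataFrame({"a": [5] * 12, "b": [0] * 11 + [7]})
        with pytest.warns(UserWarning):
            f = tmm_factors(counts, ref_sample="a")
        assert f["b"] / f["a"] == pytest.approx(1.0)


class TestInverseNormal:
    def test_blom_closed_form_n3(self):
        z = inverse_normal_transform(np.array([5.0, 1.0, 3.0]))
        c = 3.0 / 8.0
        expect = stats.norm.ppf((np.array([3, 1, 2]) - c) / (3 - 2 * c + 1))
        assert z == pytest.approx(expect)
        assert z[2] == pytest.approx(0.0)

    def test_monotone_transform_invariance(self):
        x = np.random.default_rng(1).normal(size=50)
        assert inverse_normal_transform(x) == pytest.approx(
            inverse_normal_transform(np.exp(x))
        )

    def test_median_tie_maps_to_zero(self):
        z = inverse_normal_transform(np.array([1.0, 2.0, 2.0, 3.0]))
        assert z[1] == pytest.approx(0.0) and z[2] == pytest.approx(0.0)

    def test_constant_vector_warns_zeros(self):
        with pytest.warns(UserWarning):
            z = inverse_normal_transform(np.array([1.0, 1.0, 1.0]))
        assert (z == 0).all()

    def test_output_is_normal_at_n500(self):
        ok = 0
        for seed in range(20):
            x = np.random.default_rng(seed).exponential(size=500)
            ok += stats.shapiro(inverse_normal_transform(x)).pvalue > 0.01
        assert ok >= 19

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_mean_zero_symmetric(self, vals):
        z = inverse_normal_transform(np.array(vals))
        assert abs(z.mean()) < 1e-8
        assert np.max(z) == pytest.approx(-np.min(z))
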