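"""ddCt quantification, reference stability, DE screen, z-scores."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cytofoci import expression, synth


def _cq_table(rows):
    """rows: (sample, condition, gene, cq)"""
    return pd.DataFrame(
        [dict(sample=s, condition=c, gene=g, replicate=1, cq=q)
         for s, c, g, q in rows]
    )


def _two_condition_table(target_ctrl, target_trt, refs_ctrl, refs_trt):
    rows = []
    for gene, cq in [("T", target_ctrl), ("R1", refs_ctrl[0]), ("R2", refs_ctrl[1])]:
        rows.append(("c1", "ctrl", gene, cq))
    for gene, cq in [("T", target_trt), ("R1", refs_trt[0]), ("R2", refs_trt[1])]:
        rows.append(("t1", "trt", gene, cq))
    return _cq_table(rows)


class TestDeltaDeltaCt:
    def test_condition_vs_itself_is_one(self):
        t = _two_condition_table(26.0, 24.0, (20.0, 22.0), (19.0, 21.0))
        res = expression.delta_delta_ct(t, "T", "ctrl", "ctrl", ("R1", "R2"))
        assert res.fold_change == pytest.approx(1.0, abs=1e-15)

    def test_one_cycle_shift_doubles(self):
        t = _two_condition_table(26.0, 25.0, (20.0, 22.0), (20.0, 22.0))
        res = expression.delta_delta_ct(t, "T", "trt", "ctrl", ("R1", "R2"))
        assert res.fold_change == pytest.approx(2.0, abs=1e-12)

    def test_mixed_reference_hand_oracle(self):
        # independent hand computation with explicit square roots:
        # geometric means sqrt(19*21) and sqrt(20*22)
        t = _two_condition_table(26.0, 24.0, (20.0, 22.0), (19.0, 21.0))
        res = expression.delta_delta_ct(t, "T", "trt", "ctrl", ("R1", "R2"))
        d_trt = 24.0 - math.sqrt(19.0 * 21.0)
        d_ctrl = 26.0 - math.sqrt(20.0 * 22.0)
        want = 2.0 ** (-(d_trt - d_ctrl))
        assert res.delta_delta_ct == pytest.approx(d_trt - d_ctrl, abs=1e-9)
        assert res.fold_change == pytest.approx(want, abs=1e-9)

    def test_swapping_references_is_invariant(self):
        t = _two_condition_table(26.0, 24.0, (20.0, 22.0), (19.0, 21.0))
        a = expression.delta_delta_ct(t, "T", "trt", "ctrl", ("R1", "R2"))
        b = expression.delta_delta_ct(t, "T", "trt", "ctrl", ("R2", "R1"))
        assert a.fold_change == pytest.approx(b.fold_change, rel=1e-15)

    @given(shift=st.floats(min_value=-5.0, max_value=5.0))
    @settings(max_examples=25, deadline=None)
    def test_global_cq_shift_invariance_with_stable_references(self, shift):
        # stable references (identical Cq across conditions) make the
        # nonlinear geometric-mean term cancel between conditions
        t = _two_condition_table(26.0, 24.0, (20.0, 22.0), (20.0, 22.0))
        base = expression.delta_delta_ct(t, "T", "trt", "ctrl", ("R1", "R2"))
        shifted = t.copy()
        shifted["cq"] = shifted["cq"] + shift
        moved = expression.delta_delta_ct(shifted, "T", "trt", "ctrl", ("R1", "R2"))
        assert moved.fold_change == pytest.approx(base.fold_change, rel=1e-12)

    def test_arithmetic_mode_shift_invariant_for_any_references(self):
        t = _two_condition_table(26.0, 24.0, (20.0, 22.0), (19.0, 21.0))
        a = expression.delta_delta_ct(t, "T", "trt", "ctrl", ("R1", "R2"),
                                      ref_combine="arithmetic")
        shifted = t.copy()
        shifted["cq"] += 3.7
        b = expression.delta_delta_ct(shifted, "T", "trt", "ctrl", ("R1", "R2"),
                                      ref_combine="arithmetic")
        assert a.fold_change == pytest.approx(b.fold_change, rel=1e-12)

    def test_missing_reference_is_error(self):
        t = _two_condition_table(26.0, 24.0, (20.0, 22.0), (19.0, 21.0))
        with pytest.raises(ValueError, match="missing"):
            expression.delta_delta_ct(t, "T", "trt", "ctrl", ("R1", "R9"))

    def test_nonpositive_cq_in_geometric_mean_is_error(self):
        t = _two_condition_table(26.0, 24.0, (-20.0, 22.0), (19.0, 21.0))
        with pytest.raises(ValueError, match="geometric"):
            expression.delta_delta_ct(t, "T", "trt", "ctrl", ("R1", "R2"))


class TestReferenceStability:
    def test_identical_cq_unflagged(self):
        p = synth.ExpressionTruthParams(cq_noise_sd=0.0, seed=1)
        cq = synth.generate_cq_table(p, synth.QPCRDesign())
        rep = expression.reference_stability(cq, p.reference_genes)
        assert (rep["sd_across_conditions"] == 0).all()
        assert not rep["flagged"].any()

    def test_shifted_reference_flagged(self):
        p = synth.ExpressionTruthParams(
            cq_noise_sd=0.0, reference_shifts={"Gapdh": {"8Gy": 2.0}}, seed=1
        )
        cq = synth.generate_cq_table(p, synth.QPCRDesign())
        rep = expression.reference_stability(cq, p.reference_genes).set_index("gene")
        assert rep.loc["Gapdh", "flagged"]
        assert not rep.loc["Rpl13a", "flagged"]

    def test_single_condition_is_error(self):
        p = synth.ExpressionTruthParams(seed=1)
        cq = synth.generate_cq_table(
            p, synth.QPCRDesign(conditions=("0Gy",), control_condition="0Gy")
        )
        with pytest.raises(ValueError):
            expression.reference_stability(cq, p.reference_genes)

    def test_noisy_sd_recovered(self):
        # mean Cq per condition averages n_samples*n_tech wells, so its
        # spread across conditions reflects sigma/sqrt(n_wells)
        sigma, n_wells = 0.2, 6
        design = synth.QPCRDesign(
            conditions=("a", "b", "c", "d", "e", "f", "g", "h"),
            control_condition="a", n_samples=3, n_tech_replicates=2,
        )
        sds = []
        for seed in range(30):
            p = synth.ExpressionTruthParams(cq_noise_sd=sigma, seed=seed)
            cq = synth.generate_cq_table(p, design)
            rep = expression.reference_stability(cq, p.reference_genes)
            sds.extend(rep["sd_across_conditions"].tolist())
        assert np.mean(sds) == pytest.approx(sigma / np.sqrt(n_wells), rel=0.15)


def brute_force_de(matrix, groups, ga, gb, fc_cut=1.5, p_cut=0.05, floor=0.5,
                   pc=0.1):
    """Independent gene-by-gene loop with the t statistic computed from
    first principles (pooled-variance two-sample formula)."""
    flags = {}
    a_cols = groups.index[groups == ga]
    b_cols = groups.index[groups == gb]
    for gene in matrix.index:
        a = matrix.loc[gene, a_cols].to_numpy(dtype=float)
        b = matrix.loc[gene, b_cols].to_numpy(dtype=float)
        ma, mb = a.mean(), b.mean()
        fc = mb / ma if ma > 0 else (np.inf if mb > 0 else 1.0)
        la, lb = np.log2(a + pc), np.log2(b + pc)
        na, nb = len(la), len(lb)
        sp2 = ((na - 1) * la.var(ddof=1) + (nb - 1) * lb.var(ddof=1)) / (na + nb - 2)
        if sp2 == 0:
            p = 1.0
        else:
            tt = (lb.mean() - la.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p = 2 * stats.t.sf(abs(tt), na + nb - 2)
        flags[gene] = (
            (fc >= fc_cut or fc <= 1 / fc_cut)
            and p <= p_cut
            and (ma >= floor or mb >= floor)
        )
    return flags


class TestDEFilter:
    def test_low_fpkm_gene_excluded_despite_fc_and_p(self):
        matrix = pd.DataFrame(
            {"a1": [0.01, 5.0], "a2": [0.012, 5.2], "a3": [0.011, 4.9],
             "b1": [0.04, 5.1], "b2": [0.045, 5.0], "b3": [0.043, 5.1]},
            index=["lowG", "flatG"],
        )
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=matrix.columns)
        res = expression.de_filter(matrix, groups, "A", "B")
        assert not res.loc["lowG", "passes_fpkm"]
        assert not res.loc["lowG", "de"]

    def test_boundary_cutoffs_inclusive(self):
        # FC exactly 1.5 and mean FPKM exactly 0.5 both count as passing
        matrix = pd.DataFrame(
            {"a1": [0.95, 0.05], "a2": [1.00, 0.10], "a3": [1.05, 0.15],
             "b1": [1.45, 0.45], "b2": [1.50, 0.50], "b3": [1.55, 0.55]},
            index=["fc_edge", "floor_edge"],
        )
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=matrix.columns)
        res = expression.de_filter(matrix, groups, "A", "B")
        assert res.loc["fc_edge", "fold_change"] == pytest.approx(1.5, abs=1e-12)
        assert res.loc["floor_edge", "mean_b"] == pytest.approx(0.5, abs=1e-12)
        assert res.loc["fc_edge", "de"]
        assert res.loc["floor_edge", "de"]

    def test_matches_brute_force_on_synthetic_matrix(self):
        p = synth.ExpressionTruthParams(
            n_genes=50, de_fraction=0.2, log2_effect_size=3.0,
            fpkm_log2_mean=5.0, fpkm_log2_sd=0.8, fpkm_within_sd=0.1, seed=13,
        )
        matrix, groups, truth = synth.generate_expression_matrix(p)
        res = expression.de_filter(matrix, groups, "ctrl", "irr")
        brute = brute_force_de(matrix, groups, "ctrl", "irr")
        assert res["de"].to_dict() == brute
        assert (res["de"] == truth["is_de"]).all()

    def test_invariant_to_gene_and_sample_order(self):
        p = synth.ExpressionTruthParams(n_genes=30, seed=14)
        matrix, groups, _ = synth.generate_expression_matrix(p)
        base = expression.de_filter(matrix, groups, "ctrl", "irr")
        rng = np.random.default_rng(0)
        gperm = rng.permutation(matrix.index)
        sperm = rng.permutation(matrix.columns)
        shuffled = expression.de_filter(
            matrix.loc[gperm, sperm], groups[sperm], "ctrl", "irr"
        )
        assert base["de"].sort_index().equals(shuffled["de"].sort_index())

    def test_small_group_is_error(self):
        matrix = pd.DataFrame({"a1": [1.0], "b1": [2.0], "b2": [2.0]}, index=["g"])
        groups = pd.Series(["A", "B", "B"], index=matrix.columns)
        with pytest.raises(ValueError):
            expression.de_filter(matrix, groups, "A", "B")


class TestZscore:
    def test_simple_row_normalisation(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        z, flags = expression.zscore_matrix(values)
        assert z.loc["g"].mean() == pytest.approx(0.0, abs=1e-15)
        assert z.loc["g"].std(ddof=1) == pytest.approx(1.0, abs=1e-15)
        assert not flags["g"]

    def test_constant_row_zeroed_and_flagged(self):
        values = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 4.0]],
                              index=["flat", "var"], columns=list("abc"))
        z, flags = expression.zscore_matrix(values)
        assert (z.loc["flat"] == 0).all()
        assert flags["flat"] and not flags["var"]

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_random_matrix_rows_standardised(self, seed):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(rng.normal(5, 2, (20, 6)))
        z, flags = expression.zscore_matrix(values)
        assert not flags.any()
        assert np.abs(z.mean(axis=1)).max() < 1e-12
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-12

    def test_single_condition_is_error(self):
        with pytest.raises(ValueError):
            expression.zscore_matrix(pd.DataFrame([[1.0]], columns=["only"]))
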