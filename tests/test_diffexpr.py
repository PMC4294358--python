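"""Differential-expression stage: fits, variance moderation, FDR, gating."""

from __future__ import annotations

import math
import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from overconnect import diffexpr as dx
from overconnect import run_de

from conftest import make_study, write_study_tsv


# ---------------------------------------------------------------- loading

class TestLoadExpression:
    def test_round_trip(self, tiny_study, tmp_path):
        write_study_tsv(tiny_study, tmp_path / "m.tsv", tmp_path / "s.tsv")
        study = dx.load_expression(tmp_path / "m.tsv", tmp_path / "s.tsv")
        assert study.gene_ids == tiny_study.gene_ids
        assert study.n_case == 3 and study.n_control == 3
        np.testing.assert_allclose(study.values, tiny_study.values)

    def test_orphan_sample_is_an_error(self, tiny_study, tmp_path):
        write_study_tsv(tiny_study, tmp_path / "m.tsv", tmp_path / "s.tsv")
        sheet = pd.read_csv(tmp_path / "s.tsv", sep="\t")
        sheet.iloc[1:].to_csv(tmp_path / "s.tsv", sep="\t", index=False)
        with pytest.raises(dx.ExpressionLoadError, match="case_0"):
            dx.load_expression(tmp_path / "m.tsv", tmp_path / "s.tsv")

    def test_duplicate_gene_named_in_error(self, tiny_study, tmp_path):
        write_study_tsv(tiny_study, tmp_path / "m.tsv", tmp_path / "s.tsv")
        mat = pd.read_csv(tmp_path / "m.tsv", sep="\t")
        pd.concat([mat, mat.iloc[[2]]]).to_csv(tmp_path / "m.tsv", sep="\t",
                                               index=False)
        with pytest.raises(dx.ExpressionLoadError, match="g2"):
            dx.load_expression(tmp_path / "m.tsv", tmp_path / "s.tsv")

    def test_non_numeric_cell_reported_with_position(self, tiny_study, tmp_path):
        write_study_tsv(tiny_study, tmp_path / "m.tsv", tmp_path / "s.tsv")
        mat = pd.read_csv(tmp_path / "m.tsv", sep="\t", dtype=str)
        mat.loc[1, "ctrl_2"] = "oops"
        mat.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        with pytest.raises(dx.ExpressionLoadError, match="g1.*ctrl_2"):
            dx.load_expression(tmp_path / "m.tsv", tmp_path / "s.tsv")

    def test_small_group_rejected(self):
        with pytest.raises(dx.ExpressionLoadError, match="at least 2"):
            make_study(np.ones((2, 4)), n_case=1, n_control=3)

    def test_genes_with_missing_values_dropped(self, tiny_study, tmp_path):
        write_study_tsv(tiny_study, tmp_path / "m.tsv", tmp_path / "s.tsv")
        mat = pd.read_csv(tmp_path / "m.tsv", sep="\t")
        mat.loc[0, "case_1"] = np.nan
        mat.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        study = dx.load_expression(tmp_path / "m.tsv", tmp_path / "s.tsv")
        assert study.gene_ids == ["g1", "g2", "g3"]


# ---------------------------------------------------------------- two-group fit

class TestFitTwoGroup:
    def test_zero_variance_gene(self, tiny_study):
        fit = dx.fit_two_group(tiny_study)
        assert fit.log2fc[0] == pytest.approx(1.0)
        assert fit.s2[0] == pytest.approx(0.0)
        assert fit.df == 4
        assert fit.se_unit == pytest.approx(math.sqrt(2 / 3))

    def test_identical_groups_give_zero_log2fc(self, tiny_study):
        fit = dx.fit_two_group(tiny_study)
        assert fit.log2fc[1] == pytest.approx(0.0)

    def test_pooled_variance_two_by_two(self):
        # case (3,5), control (1,1): log2fc 3, pooled s2 = 1.0, df 2
        study = make_study([[3, 5, 1, 1]], n_case=2, n_control=2)
        fit = dx.fit_two_group(study)
        assert fit.log2fc[0] == pytest.approx(3.0)
        assert fit.s2[0] == pytest.approx(1.0)
        assert fit.df == 2
        # independent route: numpy per-group variances
        expected = (np.var([3, 5], ddof=1) + np.var([1, 1], ddof=1)) / 2
        assert fit.s2[0] == pytest.approx(expected)


# ---------------------------------------------------------------- moderation

class TestModerateVariances:
    def test_identical_variances_are_returned_unchanged(self):
        prior = dx.moderate_variances(np.full(10, 0.3), df=4)
        assert math.isinf(prior.d0)
        np.testing.assert_allclose(prior.s2_post, 0.3, rtol=1e-12)

    def test_no_moderation_limit_keeps_raw_variances(self):
        s2 = np.array([0.1, 0.5, 2.0])
        np.testing.assert_allclose(dx._posterior_variances(s2, 4, 0.0, 1.0), s2)

    def test_prior_parameter_recovery(self):
        rng = np.random.default_rng(0)
        d0, s0, df, n = 4.0, 0.05, 4, 5000
        sigma2 = d0 * s0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        prior = dx.moderate_variances(s2, df)
        assert prior.d0 == pytest.approx(d0, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0, rel=0.15)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            dx.moderate_variances(np.zeros(5), df=4)

    def test_matches_limma_squeeze_and_ebayes(self, tmp_path):
        """Independent oracle: Bioconductor limma on the same matrix."""
        rng = np.random.default_rng(7)
        n = 200
        sigma2 = 0.05 * 4 / rng.chisquare(4, n)
        vals = (rng.normal(7, 1.5, n)[:, None]
                + rng.normal(0, 1, (n, 6)) * np.sqrt(sigma2)[:, None])
        vals[:50, :3] += rng.normal(0, 1, 50)[:, None]
        study = make_study(vals)
        write_study_tsv(study, tmp_path / "m.tsv", tmp_path / "s.tsv")
        rscript = tmp_path / "limma.R"
        rscript.write_text(
            'suppressMessages(library(limma))\n'
            'a <- commandArgs(trailingOnly=TRUE)\n'
            'mat <- read.delim(a[1], row.names=1, check.names=FALSE)\n'
            'g <- read.delim(a[2])\n'
            'design <- model.matrix(~0+factor(g$group, levels=c("control","case")))\n'
            'colnames(design) <- c("control","case")\n'
            'fit <- lmFit(as.matrix(mat), design)\n'
            'fit <- contrasts.fit(fit, makeContrasts(case-control, levels=design))\n'
            'fit <- eBayes(fit)\n'
            'write.table(data.frame(t=fit$t[,1], p=fit$p.value[,1],\n'
            '  d0=fit$df.prior, s0=fit$s2.prior), a[3], sep="\\t",\n'
            '  quote=FALSE, row.names=FALSE)\n'
        )
        out = tmp_path / "limma_out.tsv"
        subprocess.run(
            ["Rscript", str(rscript), str(tmp_path / "m.tsv"),
             str(tmp_path / "s.tsv"), str(out)],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(out, sep="\t")
        fit = dx.fit_two_group(study)
        prior = dx.moderate_variances(fit.s2, fit.df)
        t, p = dx.moderated_t(fit.log2fc, prior.s2_post, fit.se_unit,
                              fit.df + prior.d0)
        assert prior.d0 == pytest.approx(ref.d0[0], rel=1e-9)
        assert prior.s0_sq == pytest.approx(ref.s0[0], rel=1e-9)
        np.testing.assert_allclose(t, ref.t.to_numpy(), atol=1e-10)
        np.testing.assert_allclose(p, ref.p.to_numpy(), atol=1e-10)


class TestModeratedT:
    def test_zero_effect_gives_unit_p(self):
        t, p = dx.moderated_t(np.zeros(3), np.ones(3), 0.8, 10.0)
        np.testing.assert_allclose(t, 0.0)
        np.testing.assert_allclose(p, 1.0)

    def test_no_moderation_equals_classical_pooled_t(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(5, 1, (300, 6))
        vals[:40, :3] += 1.0
        study = make_study(vals)
        de, _ = run_de(study, moderate=False)
        ref = stats.ttest_ind(vals[:, :3], vals[:, 3:], axis=1, equal_var=True)
        np.testing.assert_allclose(de["t_mod"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(de["p_raw"], ref.pvalue, atol=1e-10)

    def test_quantile_anchor(self):
        # Student t critical value: |t| = 2.776 with 4 df sits at p ~ 0.050
        _, p = dx.moderated_t(np.array([2.776]), np.ones(1), 1.0, 4.0)
        assert p[0] == pytest.approx(0.050, abs=5e-4)

    def test_infinite_df_uses_normal_tail(self):
        _, p = dx.moderated_t(np.array([1.959964]), np.ones(1), 1.0, math.inf)
        assert p[0] == pytest.approx(0.05, abs=1e-6)


# ---------------------------------------------------------------- BH FDR

def bh_step_up(p):
    """Independent hand implementation of Benjamini-Hochberg adjustment."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestAdjustFdrBH:
    @pytest.mark.parametrize("p, expected", [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ])
    def test_worked_examples(self, p, expected):
        np.testing.assert_allclose(dx.adjust_fdr_bh(np.array(p)), expected)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_hand_step_up_and_dominates_raw(self, p):
        p = np.asarray(p)
        adj = dx.adjust_fdr_bh(p)
        np.testing.assert_allclose(adj, bh_step_up(p), atol=1e-12)
        assert np.all(adj >= p - 1e-12)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    def test_order_invariance(self, p, rnd):
        p = np.asarray(p)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        perm = np.array(perm)
        np.testing.assert_allclose(dx.adjust_fdr_bh(p)[perm],
                                   dx.adjust_fdr_bh(p[perm]), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dx.adjust_fdr_bh(np.array([0.5, 1.5]))


# ---------------------------------------------------------------- gating

class TestCallSignificant:
    @pytest.mark.parametrize("fc, p_adj, sig, direction", [
        (2.0, 0.04, True, "up"),       # threshold is inclusive
        (0.4, 0.01, True, "down"),     # max(0.4, 2.5) = 2.5 >= 2
        (3.0, 0.06, False, "none"),    # alpha gate
        (1.9, 0.001, False, "none"),   # fold-change gate
    ])
    def test_joint_gates(self, fc, p_adj, sig, direction):
        de = pd.DataFrame({"gene_id": ["g"], "fc": [fc], "p_adj": [p_adj]})
        flagged, summary = dx.call_significant(de)
        assert bool(flagged["significant"][0]) is sig
        assert flagged["direction"][0] == direction
        assert summary.n_total_de == int(sig)

    def test_summary_counts_invariant_to_gene_relabeling(self):
        rng = np.random.default_rng(3)
        de = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(50)],
            "fc": np.exp2(rng.normal(0, 1.5, 50)),
            "p_adj": rng.uniform(0, 1, 50),
        })
        _, s1 = dx.call_significant(de)
        relabeled = de.assign(gene_id=[f"x{i}" for i in range(50)])
        _, s2 = dx.call_significant(relabeled)
        assert (s1.n_total_de, s1.n_up, s1.n_down) == (
            s2.n_total_de, s2.n_up, s2.n_down)


# ---------------------------------------------------------------- invariants

def test_null_false_positive_rate_is_nominal():
    """p_raw is calibrated on pure-noise studies (pooled over seeds)."""
    hits, total = 0, 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        study = make_study(rng.normal(7, 0.5, (200, 6)))
        de, _ = run_de(study)
        hits += int((de["p_raw"] <= 0.05).sum())
        total += len(de)
    rate = hits / total
    se = math.sqrt(0.05 * 0.95 / total)
    assert abs(rate - 0.05) <= 3 * se


def test_power_on_planted_effects():
    """log2 shifts of 1.5 against sd 0.5 (3v3) are detected with power >= 0.8."""
    rng = np.random.default_rng(5)
    n, frac = 5000, 0.10
    vals = rng.normal(7, 0.5, (n, 6))
    planted = rng.choice(n, int(frac * n), replace=False)
    signs = rng.choice([-1.5, 1.5], len(planted))
    vals[planted, :3] += signs[:, None]
    de, _ = run_de(make_study(vals))
    power = de.iloc[planted]["significant"].mean()
    assert power >= 0.8
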