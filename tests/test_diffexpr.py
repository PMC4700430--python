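"""Moderated-t machinery: per-probe stats, prior fit, p-values, selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bloodtx.diffexpr import (DEGSelection, VariancePrior, de_table,
                              fit_variance_prior, moderated_t, probe_stats,
                              select_degs, signed_fold_change, top_table)
from bloodtx.datatypes import ExpressionMatrix, ProbeAnnotation
from conftest import make_matrix, make_samples


class TestProbeStats:
    def test_hand_computed_values(self, samples4):
        # columns: case01 ctrl01 case02 ctrl02
        m = make_matrix([[1.0, 0.0, 1.0, 0.0],
                         [2.0, 1.0, 0.0, -1.0]])
        st = probe_stats(m, samples4)
        assert st.loc["P0000", "log2_fc"] == 1.0
        assert st.loc["P0000", "s2"] == 0.0
        assert st.loc["P0001", "log2_fc"] == 1.0
        # case {2,0}, ctrl {1,-1}: s1^2 = s2^2 = 2 -> pooled 2
        assert st.loc["P0001", "s2"] == pytest.approx(2.0)
        assert st["df_resid"].iloc[0] == 2.0

    def test_invariant_to_sample_permutation(self, samples4):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(20, 4)))
        st1 = probe_stats(m, samples4)
        perm = rng.permutation(4)
        m2 = ExpressionMatrix(m.values.iloc[:, perm], stage="baselined")
        st2 = probe_stats(m2, samples4)
        pd.testing.assert_frame_equal(st1, st2)

    def test_small_group_rejected(self):
        m = make_matrix(np.ones((3, 2)))
        with pytest.raises(ValueError, match="2 samples"):
            probe_stats(m, make_samples(1))


class TestVariancePrior:
    def test_all_equal_gives_infinite_d0(self):
        prior = fit_variance_prior(np.full(50, 4.0), df_resid=10)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(4.0)

    def test_parameter_recovery_from_simulated_s2(self):
        rng = np.random.default_rng(11)
        d0, s0_sq, df, n = 4.0, 1.0, 26.0, 10000
        sigma2 = s0_sq * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        prior = fit_variance_prior(s2, df)
        assert prior.d0 == pytest.approx(d0, rel=0.25)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(12)
        s2 = rng.chisquare(6, 500) / 6
        p1 = fit_variance_prior(s2, 8)
        p2 = fit_variance_prior(2 * s2, 8)
        assert p2.d0 == pytest.approx(p1.d0, rel=1e-9)
        assert p2.s0_sq == pytest.approx(2 * p1.s0_sq, rel=1e-9)


class TestModeratedT:
    @staticmethod
    def _stats_frame(lfc, s2, df):
        return pd.DataFrame({"log2_fc": lfc, "s2": s2, "df_resid": float(df)},
                            index=[f"p{i}" for i in range(len(lfc))])

    def test_d0_near_zero_equals_ordinary_t(self):
        rng = np.random.default_rng(1)
        lfc = rng.normal(size=50)
        s2 = rng.chisquare(10, 50) / 10
        n1 = n2 = 7
        df = n1 + n2 - 2
        out = moderated_t(self._stats_frame(lfc, s2, df),
                          VariancePrior(1e-6, 0.5), n1, n2)
        t_ord = lfc / np.sqrt(s2 * (1 / n1 + 1 / n2))
        np.testing.assert_allclose(out["t_mod"], t_ord, rtol=1e-4)
        p_ord = 2 * sps.t.sf(np.abs(t_ord), df)
        np.testing.assert_allclose(out["p"], p_ord, rtol=1e-3)

    def test_zero_fold_change_gives_p_one(self):
        out = moderated_t(self._stats_frame([0.0], [1.0], 10),
                          VariancePrior(3.0, 0.5), 6, 6)
        assert out["t_mod"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_matches_step_by_step_oracle(self):
        rng = np.random.default_rng(2)
        d0, s0_sq, n1, n2 = 3.0, 0.5, 14, 14
        df = n1 + n2 - 2
        lfc = rng.normal(size=200)
        s2 = rng.chisquare(df, 200) / df
        out = moderated_t(self._stats_frame(lfc, s2, df),
                          VariancePrior(d0, s0_sq), n1, n2)
        for i in rng.choice(200, 20, replace=False):
            s2_post = (d0 * s0_sq + df * s2[i]) / (d0 + df)
            t = lfc[i] / np.sqrt(s2_post * (1 / n1 + 1 / n2))
            p = 2 * sps.t.sf(abs(t), df + d0)
            assert out["t_mod"].iloc[i] == pytest.approx(t, rel=1e-12)
            assert out["df_total"].iloc[i] == df + d0
            assert out["p"].iloc[i] == pytest.approx(p, rel=1e-12)

    def test_infinite_d0_uses_normal_reference(self):
        out = moderated_t(self._stats_frame([1.0], [2.0], 10),
                          VariancePrior(np.inf, 1.0), 5, 5)
        t = 1.0 / np.sqrt(1.0 * (1 / 5 + 1 / 5))
        assert out["p"].iloc[0] == pytest.approx(2 * sps.norm.sf(t), rel=1e-12)

    def test_antisymmetric_under_group_swap(self, samples14):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(100, 28)))
        det = de_table(m, samples14)
        swapped = samples14.table.copy()
        swapped["group"] = swapped["group"].map(
            {"case": "control", "control": "case"})
        from bloodtx.datatypes import SampleTable
        det2 = de_table(m, SampleTable(swapped))
        np.testing.assert_allclose(det["t_mod"], -det2["t_mod"], atol=1e-10)
        np.testing.assert_allclose(det["p"], det2["p"], atol=1e-12)

    def test_limma_oracle_agreement(self, tmp_path):
        """Cross-check the full moderated-t path against Bioconductor limma."""
        import subprocess

        rng = np.random.default_rng(8)
        n_probes, n1, n2 = 60, 6, 6
        vals = rng.normal(0, 1, size=(n_probes, n1 + n2))
        vals[:5, :n1] += 1.0
        m = make_matrix(vals)
        samples = make_samples(6)
        # make_matrix interleaves case/ctrl columns; rebuild in case-first order
        ordered = samples.case_ids + samples.control_ids
        mat = m.values[ordered]
        mat.to_csv(tmp_path / "m.tsv", sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            'x <- as.matrix(read.delim("%s", row.names = 1))\n'
            "suppressMessages(library(limma))\n"
            "design <- cbind(1, c(rep(1, %d), rep(0, %d)))\n"
            "fit <- eBayes(lmFit(x, design))\n"
            'out <- data.frame(t = fit$t[, 2], p = fit$p.value[, 2],\n'
            "                  d0 = fit$df.prior, s0 = fit$s2.prior)\n"
            'write.table(out, "%s", sep = "\\t", quote = FALSE)\n'
            % (tmp_path / "m.tsv", n1, n2, tmp_path / "limma_out.tsv")
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t")
        det = de_table(m, samples)
        np.testing.assert_allclose(det.attrs["prior_d0"], ref["d0"].iloc[0],
                                   rtol=1e-4)
        np.testing.assert_allclose(det.attrs["prior_s0_sq"], ref["s0"].iloc[0],
                                   rtol=1e-4)
        np.testing.assert_allclose(det["t_mod"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(det["p"], ref["p"], rtol=1e-6)


class TestSignedFoldChange:
    @pytest.mark.parametrize("lfc,expected", [
        (1.0, 2.0), (-1.0, -2.0), (0.0, 1.0), (2.0, 4.0),
    ])
    def test_display_convention(self, lfc, expected):
        assert signed_fold_change(lfc) == pytest.approx(expected)

    def test_down_regulation_display_value(self):
        # a -2.22 display value corresponds to log2 FC = -log2(2.22)
        assert signed_fold_change(-np.log2(2.22)) == pytest.approx(-2.22)

    def test_magnitude_at_least_one(self):
        lfc = np.linspace(-3, 3, 41)
        fc = signed_fold_change(lfc)
        assert (np.abs(fc) >= 1).all()
        np.testing.assert_allclose(np.abs(fc), np.exp2(np.abs(lfc)))
        assert (np.sign(fc[lfc != 0]) == np.sign(lfc[lfc != 0])).all()


def _det_frame(p, fc):
    return pd.DataFrame({
        "p": p, "signed_fc": fc, "log2_fc": np.log2(np.abs(fc)) * np.sign(fc),
    }, index=[f"g{i}" for i in range(len(p))])


class TestSelection:
    def test_strict_thresholds(self):
        det = _det_frame([0.005, 0.005, 0.02], [1.6, 1.5, 3.0])
        sel = select_degs(det)
        assert sel.deg_ids == ["g0"]
        assert sel.n_up == 1 and sel.n_down == 0

    def test_planted_passing_set_exactly_selected(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.02, 1.0, 100)
        fc = rng.uniform(-1.4, 1.4, 100)
        fc = np.where(np.abs(fc) < 1, 1.0, fc)
        plant = rng.choice(100, 10, replace=False)
        p[plant] = rng.uniform(1e-5, 0.009, 10)
        fc[plant] = rng.choice([-1.0, 1.0], 10) * rng.uniform(1.6, 3.0, 10)
        det = _det_frame(p, fc)
        sel = select_degs(det)
        assert set(sel.deg_ids) == {f"g{i}" for i in plant}
        assert sel.n_up + sel.n_down == 10

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        det = _det_frame(rng.uniform(0, 1, 200),
                         rng.choice([-1, 1], 200) * rng.uniform(1, 4, 200))
        tight = set(select_degs(det, 0.01, 1.5).deg_ids)
        assert tight <= set(select_degs(det, 0.05, 1.5).deg_ids)
        assert tight <= set(select_degs(det, 0.01, 1.2).deg_ids)


class TestTopTable:
    def test_sorted_by_p_then_absfc(self):
        det = _det_frame([0.3, 0.01, 0.2, 0.01], [1.1, 1.2, 1.3, -2.0])
        top = top_table(det, 2)
        assert top.index.tolist() == ["g3", "g1"]  # tie at 0.01: larger |fc|

    def test_topk_equals_full_sort_prefix(self):
        rng = np.random.default_rng(6)
        det = _det_frame(rng.uniform(0, 1, 500),
                         rng.choice([-1, 1], 500) * rng.uniform(1, 4, 500))
        top20 = top_table(det, 20)
        full = top_table(det, 500)
        assert top20.index.tolist() == full.index.tolist()[:20]

    def test_k_larger_than_table(self):
        det = _det_frame([0.1, 0.2], [1.5, 1.5])
        out = top_table(det, 10)
        assert len(out) == 2 and "note" in out.attrs

    def test_symbols_only_excludes_unannotated(self):
        det = _det_frame([0.01, 0.02, 0.03], [2.0, 2.0, 2.0])
        ann = ProbeAnnotation(pd.DataFrame(
            {"gene_symbol": ["A", None, "C"]},
            index=pd.Index(["g0", "g1", "g2"], name="probe_id")))
        out = top_table(det, 3, ann, symbols_only=True)
        assert out.index.tolist() == ["g0", "g2"]
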