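"""Moderated-t machinery: group fits, variance-prior estimation, p-values,
FDR, fold-change conventions, threshold scheme, and the limma cross-check."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from conftest import make_dataset
from oracles import bh_fdr_brute, classical_t_brute
from tempomir.diffexpr import (
    EBayesHyper,
    ModeratedTTest,
    bh_fdr,
    call_de,
    estimate_hyperparameters,
    fit_group_means,
    moderated_t,
    signed_fold_change,
)


class TestGroupMeans:
    def test_hand_computed_fixture(self):
        x = np.array([[8.1, 8.3, 8.2, 8.4, 8.0, 8.1, 7.9, 8.0]])
        ds = make_dataset(x, n_treated=4)
        out = fit_group_means(ds, "AMY", 0)
        assert out["beta"].iloc[0] == pytest.approx(0.25, abs=1e-12)
        vt = np.var([8.1, 8.3, 8.2, 8.4], ddof=1)
        vc = np.var([8.0, 8.1, 7.9, 8.0], ddof=1)
        assert out["s2"].iloc[0] == pytest.approx((3 * vt + 3 * vc) / 6, abs=1e-12)
        assert out["d"].iloc[0] == 6
        assert out["v"].iloc[0] == pytest.approx(0.5)

    def test_equal_groups_give_zero_beta(self):
        rng = np.random.default_rng(0)
        half = rng.normal(8, 1, (20, 5))
        ds = make_dataset(np.hstack([half, half]), n_treated=5)
        out = fit_group_means(ds, "AMY", 0)
        np.testing.assert_allclose(out["beta"], 0.0, atol=1e-12)

    def test_scaling_linearity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(8, 1, (15, 10))
        a = fit_group_means(make_dataset(x), "AMY", 0)
        b = fit_group_means(make_dataset(2 * x), "AMY", 0)
        np.testing.assert_allclose(b["beta"], 2 * a["beta"], rtol=1e-10)
        np.testing.assert_allclose(b["s2"], 4 * a["s2"], rtol=1e-10)

    def test_small_group_raises_naming_contrast(self):
        ds = make_dataset(np.ones((3, 4)), n_treated=1)
        with pytest.raises(ValueError, match="AMY/0h"):
            fit_group_means(ds, "AMY", 0)


class TestHyperparameters:
    def test_parameter_recovery(self):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            d0, s0, G, d = 4.0, 0.05, 5000, 14
            s2 = s0 * (d0 / rng.chisquare(d0, G)) * (rng.chisquare(d, G) / d)
            h = estimate_hyperparameters(s2, d)
            assert abs(h.d0 - d0) / d0 < 0.20
            assert abs(h.s0_sq - s0) / s0 < 0.20

    def test_identical_variances_give_infinite_d0(self):
        h = estimate_hyperparameters(np.full(50, 0.3), 10)
        assert np.isinf(h.d0)
        assert h.s0_sq == pytest.approx(0.3)

    def test_small_heterogeneous_sample_satisfies_moment_equations(self):
        rng = np.random.default_rng(3)
        s2 = rng.chisquare(5, 10) / 5 * 0.2
        d = 8.0
        h = estimate_hyperparameters(s2, d)
        assert np.isfinite(h.d0) and h.d0 > 0
        e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
        excess = e.var(ddof=1) - special.polygamma(1, d / 2)
        # the trigamma equation holds at the returned d0
        assert special.polygamma(1, h.d0 / 2) == pytest.approx(excess, abs=1e-8)
        assert h.s0_sq == pytest.approx(
            np.exp(e.mean() + special.digamma(h.d0 / 2) - np.log(h.d0 / 2)), rel=1e-10
        )

    def test_zero_variances_excluded_with_warning(self):
        s2 = np.concatenate([np.zeros(3), np.random.default_rng(0).chisquare(5, 40)])
        with pytest.warns(UserWarning, match="zero/invalid"):
            h = estimate_hyperparameters(s2, 10)
        assert h.s0_sq > 0


class TestModeratedT:
    @pytest.fixture()
    def fixture_fit(self):
        rng = np.random.default_rng(7)
        x = rng.normal(8, 0.5, (100, 16))
        x[:30, :8] += rng.uniform(-0.5, 0.5, (30, 1))
        ds = make_dataset(x, n_treated=8)
        return x, fit_group_means(ds, "AMY", 0)

    def test_d0_zero_equals_classical_t(self, fixture_fit):
        x, fit = fixture_fit
        out = moderated_t(fit["beta"], fit["s2"], fit["d"], fit["v"], EBayesHyper(0.0, 1.0))
        t_ref, p_ref = classical_t_brute(x[:, :8], x[:, 8:])
        np.testing.assert_allclose(out["t_mod"], t_ref, atol=1e-10)
        np.testing.assert_allclose(out["p"], p_ref, atol=1e-10)

    def test_d0_infinite_uses_normal_tail(self, fixture_fit):
        _, fit = fixture_fit
        s0 = 0.3
        out = moderated_t(fit["beta"], fit["s2"], fit["d"], fit["v"], EBayesHyper(np.inf, s0))
        expected_t = fit["beta"] / np.sqrt(s0 * fit["v"])
        np.testing.assert_allclose(out["t_mod"], expected_t, atol=1e-12)
        np.testing.assert_allclose(out["p"], 2 * stats.norm.sf(np.abs(expected_t)), atol=1e-12)

    def test_zero_beta_gives_t_zero_p_one(self):
        out = moderated_t(np.array([0.0]), np.array([0.2]), 6, 0.5, EBayesHyper(4.0, 0.1))
        assert out["t_mod"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_increasing_d0_moves_t_monotonically_to_limit(self, fixture_fit):
        _, fit = fixture_fit
        s0 = 0.4
        limit = (fit["beta"] / np.sqrt(s0 * fit["v"])).to_numpy()
        prev = None
        for d0 in (0.5, 2.0, 8.0, 32.0, 128.0):
            t = moderated_t(fit["beta"], fit["s2"], fit["d"], fit["v"], EBayesHyper(d0, s0))[
                "t_mod"
            ].to_numpy()
            if prev is not None:
                assert np.all(np.abs(limit - t) <= np.abs(limit - prev) + 1e-12)
            prev = t

    def test_s2_post_between_s2_and_prior(self, fixture_fit):
        _, fit = fixture_fit
        h = estimate_hyperparameters(fit["s2"].to_numpy(), fit["d"].to_numpy())
        res = ModeratedTTest(fit["beta"], fit["s2"], fit["d"], fit["v"]).fit(h)
        lo = np.minimum(fit["s2"], h.s0_sq)
        hi = np.maximum(fit["s2"], h.s0_sq)
        s2p = res.table["s2_post"].to_numpy()
        assert np.all(s2p >= lo - 1e-12) and np.all(s2p <= hi + 1e-12)
        assert np.all(res.table["fdr"] >= res.table["p"] - 1e-15)

    def test_summary_reports_hyperparameters(self, fixture_fit):
        _, fit = fixture_fit
        res = ModeratedTTest(fit["beta"], fit["s2"], fit["d"], fit["v"]).fit()
        text = res.summary()
        assert "prior df d0" in text and "probes:         100" in text


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_moderated_t_matches_limma_reference(tmp_path):
    """Independent cross-check of the full fit against the Bioconductor
    reference implementation on a small heteroscedastic fixture."""
    rng = np.random.default_rng(11)
    G, n1, n2, d0, s0 = 60, 5, 5, 5.0, 0.3
    sig2 = s0 * d0 / rng.chisquare(d0, G)
    x = rng.normal(0, np.sqrt(sig2)[:, None], (G, n1 + n2)) + 8
    x[:, :n1] += rng.uniform(-0.8, 0.8, (G, 1))
    xfile = tmp_path / "x.tsv"
    np.savetxt(xfile, x, delimiter="\t")
    rscript = tmp_path / "fit.R"
    rscript.write_text(
        f'x <- as.matrix(read.table("{xfile}", sep="\\t"))\n'
        "suppressMessages(library(limma))\n"
        f"design <- cbind(Intercept=1, Trt=c(rep(1,{n1}), rep(0,{n2})))\n"
        "fit <- eBayes(lmFit(x, design))\n"
        'out <- data.frame(t=fit$t[,"Trt"], p=fit$p.value[,"Trt"], d0=fit$df.prior, s0=fit$s2.prior)\n'
        f'write.table(format(out, digits=15), "{tmp_path / "out.tsv"}", sep="\\t", quote=FALSE, row.names=FALSE)\n'
    )
    proc = subprocess.run(["Rscript", str(rscript)], capture_output=True, text=True, timeout=300)
    assert proc.returncode == 0, proc.stderr
    ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
    res = ModeratedTTest.from_dataset(make_dataset(x, n_treated=n1), "AMY", 0).fit()
    assert res.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-9)
    assert res.s0_sq == pytest.approx(float(ref["s0"].iloc[0]), rel=1e-9)
    np.testing.assert_allclose(res.table["t_mod"], ref["t"], atol=1e-9)
    np.testing.assert_allclose(res.table["p"], ref["p"], atol=1e-9)


class TestFDRAndFoldChange:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_equal_p(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=12),
        st.randoms(use_true_random=False),
    )
    def test_matches_brute_force_and_permutation_invariant(self, p, rnd):
        p = np.array(p)
        np.testing.assert_allclose(bh_fdr(p), bh_fdr_brute(p), atol=1e-12)
        perm = np.array(rnd.sample(range(len(p)), len(p)))
        np.testing.assert_allclose(bh_fdr(p[perm]), bh_fdr(p)[perm], atol=1e-12)

    def test_signed_fold_change_conventions(self):
        np.testing.assert_allclose(
            signed_fold_change([0.0, 1.0, -1.0]), [1.0, 2.0, -2.0], atol=1e-12
        )
        # a treated/control ratio of 1/1.35 reports as -1.35
        assert signed_fold_change(np.log2(1 / 1.35)) == pytest.approx(-1.35)
        beta = np.linspace(-2, 2, 41)
        fc = signed_fold_change(beta)
        assert np.all(np.abs(fc) >= 1.0)
        assert np.all(np.sign(fc[beta != 0]) == np.sign(beta[beta != 0]))


class TestCallDE:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["annotation", "p", "fdr"])

    def test_mrna_early_times_use_fdr(self):
        res = call_de(self._frame([["g1", 0.01, 0.08]]), role="mrna", time_h=8)
        assert not res["is_de"].iloc[0]

    def test_mrna_late_time_uses_nominal_p(self):
        res = call_de(self._frame([["g1", 0.049, 0.40]]), role="mrna", time_h=120)
        assert res["is_de"].iloc[0]

    def test_mirna_always_nominal_inclusive(self):
        res = call_de(self._frame([["m1", 0.05, 0.3], ["m2", 0.051, 0.3]]), role="mirna", time_h=0)
        assert res.set_index("annotation")["is_de"].to_dict() == {"m1": True, "m2": False}

    def test_duplicate_probes_resolved_by_minimum_p(self):
        res = call_de(
            self._frame([["g1", 0.20, 0.5], ["g1", 0.03, 0.2], ["g2", 0.9, 0.9]]),
            role="mrna",
            time_h=120,
        )
        assert len(res) == 2
        assert res.set_index("annotation")["p"].to_dict() == {"g1": 0.03, "g2": 0.9}

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="unknown role"):
            call_de(self._frame([["g", 0.1, 0.1]]), role="protein", time_h=0)
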