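import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cyclenet import diffexpr, simulate
from conftest import small_params


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = diffexpr.quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)

    def test_hand_computed_rank_means(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = diffexpr.quantile_normalize(m)
        assert list(out["a"]) == [2.5, 3.5, 4.5]
        assert list(out["b"]) == [2.5, 3.5, 4.5]

    def test_columns_share_sorted_vector(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(50, 4)))
        out = diffexpr.quantile_normalize(m).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            assert np.allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_ties_get_mean_of_rank_range(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [10.0, 20.0, 30.0]})
        out = diffexpr.quantile_normalize(m)
        ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)
        assert out["a"].iloc[0] == out["a"].iloc[1] == pytest.approx(
            0.5 * (ref[0] + ref[1]))

    def test_single_column_warns_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = diffexpr.quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)


def _toy_compendium(values: dict, batch="b1"):
    """values: sample_id -> (target, is_control, gene values list)."""
    genes = [f"g{i}" for i in range(len(next(iter(values.values()))[2]))]
    comp = pd.DataFrame({s: v[2] for s, v in values.items()}, index=genes)
    sheet = pd.DataFrame({
        "sample_id": list(values),
        "batch": batch,
        "target_gene": [v[0] for v in values.values()],
        "is_control": [v[1] for v in values.values()],
    })
    from cyclenet.io import validate_sample_sheet
    return comp, validate_sample_sheet(sheet)


class TestBatchContrasts:
    def test_hand_example_replicated(self):
        comp, sheet = _toy_compendium({
            "t1": ("gX", False, [5.0]), "t2": ("gX", False, [5.0]),
            "c1": ("NONE", True, [3.0]), "c2": ("NONE", True, [3.0]),
            "c3": ("NONE", True, [3.0]), "c4": ("NONE", True, [3.0]),
        })
        contrasts, s2, df = diffexpr.fit_batch_contrasts(comp, sheet)
        assert contrasts["logfc"].iloc[0] == pytest.approx(2.0)
        assert s2.iloc[0] == pytest.approx(0.0)
        assert df == 4

    def test_hand_example_singlicate(self):
        comp, sheet = _toy_compendium({
            "t1": ("gX", False, [4.0]),
            "c1": ("NONE", True, [1.0]), "c2": ("NONE", True, [3.0]),
        })
        contrasts, s2, df = diffexpr.fit_batch_contrasts(comp, sheet)
        assert contrasts["logfc"].iloc[0] == pytest.approx(2.0)
        assert df == 1
        assert s2.iloc[0] == pytest.approx(2.0)  # (1-2)^2 + (3-2)^2 over 1 df

    def test_treated_equal_controls_zero_logfc(self):
        comp, sheet = _toy_compendium({
            "t1": ("gX", False, [3.0]),
            "c1": ("NONE", True, [3.0]), "c2": ("NONE", True, [3.0]),
        })
        contrasts, _, _ = diffexpr.fit_batch_contrasts(comp, sheet)
        assert contrasts["logfc"].iloc[0] == 0.0

    def test_batch_offsets_cancel(self):
        """Adding any per-(gene, batch) constant leaves all logfc unchanged."""
        params = small_params()
        comp, sheet, _ = simulate.generate_compendium(params, seed=3)
        c1, _, _ = diffexpr.fit_batch_contrasts(comp, sheet)
        rng = np.random.default_rng(0)
        shifted = comp.copy()
        for batch, grp in sheet.groupby("batch"):
            shifted[grp["sample_id"]] = (
                shifted[grp["sample_id"]]
                + rng.normal(size=(len(comp), 1)) * 5.0
            )
        c2, _, _ = diffexpr.fit_batch_contrasts(shifted, sheet)
        assert np.allclose(c1["logfc"], c2["logfc"], atol=1e-9)


class TestModeration:
    def test_infinite_prior_complete_shrinkage(self):
        rng = np.random.default_rng(1)
        # equal true variances -> underdispersed log-variances -> d0 = inf
        s2 = pd.Series(1.0 * rng.chisquare(50, 2000) / 50)
        mv = diffexpr.moderate_variances(s2, 50.0)
        if np.isinf(mv.d0):
            assert np.allclose(mv.s2_post, mv.s0_sq)
        else:
            # large but finite prior df still means strong shrinkage
            assert mv.d0 > 50

    def test_zero_prior_no_shrinkage_matches_ordinary_t(self):
        """With d0 forced to 0 the moderated t equals the ordinary t."""
        rng = np.random.default_rng(2)
        s2 = pd.Series(rng.chisquare(4, 100) / 4)
        mv = diffexpr.moderate_variances(s2, 4.0)
        mv0 = diffexpr.ModeratedVariance(d0=0.0, s0_sq=mv.s0_sq,
                                         s2_post=s2, df=4.0)
        logfc = rng.normal(size=100)
        scale = np.full(100, 1.25)
        t_mod, _ = diffexpr.moderated_t(logfc, scale, mv0)
        t_ord = logfc / np.sqrt(s2.to_numpy() * scale)
        assert np.allclose(t_mod, t_ord, atol=1e-10)

    def test_hyperparameter_recovery(self):
        """(d0, s0^2) recovered from 5000 genes simulated at (4, 1)."""
        rng = np.random.default_rng(42)
        d0, s0_sq, df, n = 4.0, 1.0, 8.0, 5000
        sigma2 = d0 * s0_sq / rng.chisquare(d0, n)
        s2 = pd.Series(sigma2 * rng.chisquare(df, n) / df)
        mv = diffexpr.moderate_variances(s2, df)
        assert mv.d0 == pytest.approx(d0, rel=0.25)
        assert mv.s0_sq == pytest.approx(s0_sq, rel=0.10)

    def test_posterior_between_prior_and_sample(self):
        rng = np.random.default_rng(3)
        s2 = pd.Series(rng.chisquare(4, 500) / 4)
        mv = diffexpr.moderate_variances(s2, 4.0)
        lo = np.minimum(s2.to_numpy(), mv.s0_sq)
        hi = np.maximum(s2.to_numpy(), mv.s0_sq)
        post = mv.s2_post.to_numpy()
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_all_zero_variances_fallback_flagged(self):
        s2 = pd.Series(np.zeros(100))
        mv = diffexpr.moderate_variances(s2, 4.0)
        assert mv.fallback
        assert (mv.s2_post > 0).all()

    def test_agrees_with_limma_squeezevar(self, tmp_path):
        """Independent oracle: the Bioconductor limma implementation of the
        same empirical-Bayes fit on a shared fixture."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; limma oracle cannot run")
        rng = np.random.default_rng(7)
        d0, s0_sq, df = 6.0, 0.5, 10.0
        sigma2 = d0 * s0_sq / rng.chisquare(d0, 800)
        s2 = sigma2 * rng.chisquare(df, 800) / df
        fixture = tmp_path / "s2.csv"
        pd.DataFrame({"s2": s2}).to_csv(fixture, index=False)
        script = tmp_path / "squeeze.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"s2 <- read.csv('{fixture}')$s2\n"
            f"fit <- squeezeVar(s2, df={df})\n"
            "cat(sprintf('%.10g %.10g', fit$df.prior, fit$var.prior))\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout.split()
        d0_r, s0_r = float(out[0]), float(out[1])
        mv = diffexpr.moderate_variances(pd.Series(s2), df)
        assert mv.d0 == pytest.approx(d0_r, rel=1e-4)
        assert mv.s0_sq == pytest.approx(s0_r, rel=1e-4)


class TestBHAdjust:
    def test_single_p_identity(self):
        assert diffexpr.bh_adjust(np.array([0.04]))[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        adj = diffexpr.bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert (diffexpr.bh_adjust(np.ones(5)) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.bh_adjust(np.array([0.5, 1.5]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_permutation_invariance(self, ps):
        """Permute -> adjust -> unpermute equals adjust."""
        p = np.asarray(ps)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        direct = diffexpr.bh_adjust(p)
        via = np.empty_like(direct)
        via[perm] = diffexpr.bh_adjust(p[perm])
        assert np.allclose(direct, via, atol=1e-12)


class TestSignificantSets:
    @pytest.fixture
    def de_frame(self):
        return pd.DataFrame({
            "experiment_id": "e1",
            "gene": ["a", "b", "c", "d"],
            "logfc": [0.31, 0.30, -0.8, 0.9],
            "t": [3.0, 3.0, -5.0, 1.0],
            "p": [0.001, 0.001, 0.0001, 0.2],
            "adj_p": [0.005, 0.005, 0.001, 0.4],
        })

    def test_strict_threshold_boundaries(self, de_frame):
        ss = diffexpr.significant_set(de_frame, "e1", 0.3, 0.01)
        # b sits exactly at 0.3 (strict >), d fails the adjusted-P rule
        assert ss.entries == {"a": 1, "c": -1}

    def test_sign_matches_logfc(self, de_frame):
        ss = diffexpr.significant_set(de_frame, "e1", 0.3, 0.01)
        assert ss.entries["c"] == -1 and ss.entries["a"] == 1

    def test_zero_noise_sets_equal_planted(self, zero_noise_run, config):
        truth = zero_noise_run["truth"]
        for e, ss in zero_noise_run["sig_overlap"].items():
            planted = truth.planted_significant_set(
                e, config.lfc_threshold_overlap)
            assert ss.entries == planted


class TestSelfKnockdownRank:
    def test_minimum_logfc_is_rank_one(self):
        genes = ["target"] + [f"g{i}" for i in range(199)]
        de = pd.DataFrame({
            "experiment_id": "e1", "gene": genes,
            "logfc": [-3.0] + list(np.linspace(-0.5, 0.5, 199)),
            "t": 0, "p": 1, "adj_p": 1,
        })
        r = diffexpr.self_knockdown_rank(de, "e1", "target")
        assert r["rank"] == 1 and r["flag"]

    def test_absent_target_returns_none(self):
        de = pd.DataFrame({
            "experiment_id": "e1", "gene": ["a"], "logfc": [0.0],
            "t": 0, "p": 1, "adj_p": 1,
        })
        assert diffexpr.self_knockdown_rank(de, "e1", "missing") is None

    def test_default_conditions_flag_rate(self, default_run):
        """At the default planted self effect and noise, nearly every
        knockdown ranks its own target in the top 1% of down-regulation."""
        sheet = default_run["sheet"]
        de = default_run["de"]
        targets = sheet[~sheet["is_control"]].drop_duplicates("experiment_id")
        flags = [
            diffexpr.self_knockdown_rank(de, e, t)["flag"]
            for e, t in zip(targets["experiment_id"], targets["target_gene"])
        ]
        assert np.mean(flags) >= 0.95


class TestShortlist:
    def _sets(self, counts):
        sets = {}
        for i in range(max(counts.values(), default=0)):
            entries = {g: 1 for g, c in counts.items() if c > i}
            sets[f"e{i}"] = diffexpr.SignificantSet(f"e{i}", entries, 0.5, 0.01)
        return sets

    def test_boundary_inclusive(self):
        sets = self._sets({"in5": 5, "in4": 4, "in6": 6})
        short = diffexpr.shortlist_genes(sets, 5)
        assert short == ["in5", "in6"]

    def test_zero_noise_shortlist_is_planted_recurrent(self, zero_noise_run,
                                                       config):
        """Noise-free shortlist = genes planted above the cluster threshold
        in at least five experiments; singleton responders are excluded."""
        truth = zero_noise_run["truth"]
        counts = (truth.planted_effects.abs()
                  > config.lfc_threshold_cluster).sum(axis=1)
        expected = sorted(counts[counts >= config.min_experiments].index)
        assert zero_noise_run["shortlist"] == expected
        targets = {e.removeprefix("kd_")
                   for e in truth.uncoupled_experiments}
        assert not targets & set(zero_noise_run["shortlist"])


class TestNullCalibration:
    def test_moderated_t_uniform_under_global_null(self):
        """With no planted effects, the fraction of raw p below alpha stays
        inside the 99% binomial interval of alpha."""
        params = small_params(n_genes=800)
        import dataclasses
        params = dataclasses.replace(
            params, phenotype_coupling=0.0, n_uncoupled=0)
        comp, sheet, truth = simulate.generate_compendium(params, seed=11)
        # remove planted effects: regenerate expression as pure noise around
        # baseline + batch; easiest is to subtract the planted effects
        sheet_ix = sheet.set_index("sample_id")
        for s in comp.columns:
            e = sheet_ix.loc[s, "experiment_id"]
            if not sheet_ix.loc[s, "is_control"]:
                comp[s] = comp[s] - truth.planted_effects[e]
        de = diffexpr.run_de(comp, sheet)
        for alpha in (0.05, 0.01):
            frac = (de["p"] < alpha).mean()
            n = len(de)
            half = 2.576 * np.sqrt(alpha * (1 - alpha) / n)
            assert abs(frac - alpha) < half + 0.002
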