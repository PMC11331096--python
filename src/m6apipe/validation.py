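"""End-to-end benchmark scenarios on synthetic data with known truth.

Each function simulates a complete scenario, runs the corresponding
pipeline stage(s) and measures recovery of the planted ground truth.
They are used both by the test suite and by ``scripts/acceptance.py``;
problem sizes default to the scenarios the package is validated on
(see docs/methods.md).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import clip as clipmod
from . import compare, te
from .coverage import window_table
from .decay import fit_decay_cohort
from .m6a import call_m6a_peaks, match_intervals
from .simulate import (
    SyntheticTruth,
    generate_transcriptome,
    plant_peaks,
    simulate_decay_timecourse,
    simulate_ip_input_coverage,
    simulate_polysome_pairs,
)

__all__ = [
    "m6a_recovery",
    "clip_recovery",
    "clip_null_zero_site_rate",
    "decay_recovery",
    "te_recovery",
    "induction_null_fraction",
    "mannwhitney_null_uniformity",
    "fip37_like_cohort",
]


def _truth_intervals(truth: dict[str, SyntheticTruth]) -> dict[str, list[tuple[int, int]]]:
    return {tid: [(p.start, p.end) for p in t.planted_peaks] for tid, t in truth.items()}


def m6a_recovery(
    seed: int,
    n_transcripts: int = 200,
    gamma: float = 8.0,
    depth: float = 100.0,
    n_replicates: int = 3,
    null: bool = False,
) -> dict[str, float]:
    """m6A caller recall/precision against planted peaks.

    The null variant plants no peaks (equivalently gamma = 1 everywhere)
    and reports the fraction of transcripts acquiring any putative site.
    """
    rng = np.random.default_rng(seed)
    models, seqs = generate_transcriptome(n_transcripts, (300, 2000), seed=rng)
    truth, seqs = plant_peaks(
        models, seqs, peak_rate=0.0 if null else 1.0, motif="RRACH",
        stop_bias=0.8, peak_width=150, gamma=gamma, seed=rng,
    )
    windows, _ = simulate_ip_input_coverage(
        models, truth, depth=depth, n_replicates=n_replicates,
        window_length=100, step=50, seed=rng,
    )
    ip = [f"ip_rep{r}" for r in range(1, n_replicates + 1)]
    inp = [f"input_rep{r}" for r in range(1, n_replicates + 1)]
    peaks = call_m6a_peaks(windows, ip, inp)
    out: dict[str, float] = {"n_transcripts": n_transcripts}
    if null:
        out["site_transcript_fraction"] = (
            peaks["transcript_id"].nunique() / n_transcripts if len(peaks) else 0.0
        )
    else:
        recall, precision = match_intervals(peaks, _truth_intervals(truth))
        out.update(recall=recall, precision=precision,
                   n_planted=sum(len(t.planted_peaks) for t in truth.values()))
    return out


def _clip_call(
    seed,
    n_transcripts: int,
    gamma: float,
    depth: float,
    null: bool,
    window_length: int = 30,
    step: int = 10,
):
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    models, seqs = generate_transcriptome(n_transcripts, (300, 2000), seed=rng)
    truth, seqs = plant_peaks(
        models, seqs, peak_rate=0.0 if null else 1.0, motif="UGUA",
        stop_bias=0.8, peak_width=50, gamma=gamma, seed=rng,
    )
    windows, _ = simulate_ip_input_coverage(
        models, truth, depth=depth, n_replicates=2, window_length=window_length,
        step=step, control=True, n_control=2, seed=rng,
    )
    sites, stats = clipmod.call_clip_sites(
        windows, ["ip_rep1", "ip_rep2"], ["input_rep1", "input_rep2"],
        ["control_rep1", "control_rep2"],
    )
    return truth, sites, stats


def clip_recovery(
    seed: int, n_transcripts: int = 200, gamma: float = 10.0, depth: float = 200.0
) -> dict[str, float]:
    """CLIP caller recall/precision against planted binding sites."""
    truth, sites, _ = _clip_call(seed, n_transcripts, gamma, depth, null=False)
    recall, precision = match_intervals(sites, _truth_intervals(truth))
    return {
        "recall": recall,
        "precision": precision,
        "n_transcripts": n_transcripts,
        "n_planted": sum(len(t.planted_peaks) for t in truth.values()),
    }


def clip_null_zero_site_rate(
    seed: int, n_runs: int = 200, n_transcripts: int = 40, depth: float = 200.0
) -> dict[str, float]:
    """Fraction of null runs (IP exchangeable with input) with zero sites."""
    rng = np.random.default_rng(seed)
    zero = 0
    for _ in range(n_runs):
        _, sites, _ = _clip_call(rng, n_transcripts, 1.0, depth, null=True)
        zero += int(len(sites) == 0)
    return {"zero_site_run_fraction": zero / n_runs, "n_runs": n_runs}


def decay_recovery(
    seed: int,
    n_transcripts: int = 500,
    timepoints=(0, 60, 120, 240),
    n_replicates: int = 3,
    noise_cv: float = 0.1,
    depth: float = 500.0,
) -> dict[str, float]:
    """Decay parameter recovery on a single-genotype beta = 0 cohort.

    True half-lives are log-uniform on [30, 480] min.
    """
    rng = np.random.default_rng(seed)
    halflives = np.exp(rng.uniform(np.log(30), np.log(480), size=n_transcripts))
    truth = {
        f"T{i:05d}": SyntheticTruth(
            f"T{i:05d}", alpha_true={"WT": float(np.log(2) / h)}, beta_true={"WT": 0.0}
        )
        for i, h in enumerate(halflives)
    }
    counts, meta = simulate_decay_timecourse(
        truth, ["WT"], timepoints, n_replicates, depth, noise_cv, seed=rng
    )
    fits = fit_decay_cohort(counts, meta, seed=int(rng.integers(2**31)))
    alpha_true = np.array([truth[tid].alpha_true["WT"] for tid in fits["transcript_id"]])
    rel_err = np.abs(fits["alpha_WT"].to_numpy() - alpha_true) / alpha_true
    beta_zero = fits["model_id"].str.endswith("beta_zero").mean()
    halflife_identity = np.allclose(
        fits["halflife_WT"], np.log(2) / fits["alpha_WT"], rtol=0, atol=0
    )
    return {
        "alpha_median_rel_error": float(np.median(rel_err)),
        "beta_zero_selected_fraction": float(beta_zero),
        "halflife_identity_exact": float(halflife_identity),
        "n_fitted": len(fits),
    }


def te_recovery(
    seed: int, n_transcripts: int = 500, depth: float = 500.0
) -> dict[str, float]:
    """Rank correlation of estimated TE against truth spanning [0.25, 4]."""
    rng = np.random.default_rng(seed)
    te_true = np.exp(rng.uniform(np.log(0.25), np.log(4), size=n_transcripts))
    truth = {
        f"T{i:05d}": SyntheticTruth(f"T{i:05d}", te_true={"mock": float(v)})
        for i, v in enumerate(te_true)
    }
    counts, meta = simulate_polysome_pairs(truth, conditions=("mock",), depth=depth, seed=rng)
    result = te.compute_te(counts, meta, "mock")
    truth_series = pd.Series(
        {tid: truth[tid].te_true["mock"] for tid in result["transcript_id"]}
    )
    rho = sps.spearmanr(result["te_mean"], truth_series[result["transcript_id"]]).statistic
    return {"te_rank_correlation": float(rho), "n_transcripts": n_transcripts}


def induction_null_fraction(
    seed: int, n_genes: int = 500, n_runs: int = 20, depth: float = 500.0
) -> dict[str, float]:
    """Fraction of inducible calls when no gene is truly induced."""
    rng = np.random.default_rng(seed)
    total = 0
    for _ in range(n_runs):
        truth = {
            f"T{i:05d}": SyntheticTruth(
                f"T{i:05d}", te_true={"mock": 1.0, "elf18": 1.0}, induction_fc_true=1.0
            )
            for i in range(n_genes)
        }
        counts, meta = simulate_polysome_pairs(truth, depth=depth, seed=rng)
        calls = te.call_inducible(counts, meta)
        total += int(calls["inducible"].sum())
    return {"inducible_fraction": total / (n_genes * n_runs), "n_runs": n_runs}


def mannwhitney_null_uniformity(
    seed: int, n_runs: int = 500, group_size: int = 40
) -> dict[str, float]:
    """KS p-value of label-shuffled Mann-Whitney p-values vs uniform."""
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_runs)
    for i in range(n_runs):
        pooled = rng.normal(size=2 * group_size)
        rng.shuffle(pooled)
        res = compare.mann_whitney(pooled[:group_size], pooled[group_size:])
        pvals[i] = res.p
    ks = sps.kstest(pvals, "uniform")
    return {"ks_p": float(ks.pvalue), "n_runs": n_runs}


def fip37_like_cohort(
    seed: int,
    n_targets: int = 300,
    n_controls: int = 300,
    depth: float = 500.0,
) -> dict[str, float]:
    """Integration scenario: a writer-mutant-like cohort.

    Inducible target transcripts have their initial decay rate halved
    (half-life doubled) and their TE halved in the mutant; control
    transcripts are unchanged and not induced.  Reports the fraction of
    inducible-target points in the (longer half-life, lower TE)
    quadrant and Mann-Whitney p-values of the target-vs-control shifts
    on both axes.
    """
    rng = np.random.default_rng(seed)
    n = n_targets + n_controls
    halflives = np.exp(rng.uniform(np.log(60), np.log(360), size=n))
    te_wt = np.exp(rng.uniform(np.log(0.5), np.log(2), size=n))
    truth_decay: dict[str, SyntheticTruth] = {}
    truth_te_wt: dict[str, SyntheticTruth] = {}
    truth_te_mut: dict[str, SyntheticTruth] = {}
    target_ids, control_ids = [], []
    for i in range(n):
        tid = f"T{i:05d}"
        is_target = i < n_targets
        (target_ids if is_target else control_ids).append(tid)
        a_wt = float(np.log(2) / halflives[i])
        a_mut = a_wt / 2 if is_target else a_wt
        fc = 4.0 if is_target else 1.0
        te_mut = te_wt[i] / 2 if is_target else te_wt[i]
        truth_decay[tid] = SyntheticTruth(
            tid, alpha_true={"WT": a_wt, "fip37": a_mut},
            beta_true={"WT": 0.0, "fip37": 0.0},
        )
        truth_te_wt[tid] = SyntheticTruth(
            tid, te_true={"mock": float(te_wt[i]), "elf18": float(te_wt[i])},
            induction_fc_true=fc,
        )
        truth_te_mut[tid] = SyntheticTruth(
            tid, te_true={"mock": float(te_mut), "elf18": float(te_mut)},
            induction_fc_true=fc,
        )

    # decay under the treated condition, both genotypes fitted jointly
    counts, meta = simulate_decay_timecourse(
        truth_decay, ["WT", "fip37"], depth=depth, seed=rng
    )
    fits = fit_decay_cohort(counts, meta, seed=int(rng.integers(2**31)))
    from .decay import halflife_change

    dhalf = halflife_change(fits, "fip37", "WT")

    # TE per genotype; inducibility from the WT input libraries
    counts_wt, meta_wt = simulate_polysome_pairs(
        truth_te_wt, depth=depth, genotype="WT", seed=rng
    )
    counts_mut, meta_mut = simulate_polysome_pairs(
        truth_te_mut, depth=depth, genotype="fip37", seed=rng
    )
    te_wt_tab = te.compute_te(counts_wt, meta_wt, "elf18")
    te_mut_tab = te.compute_te(counts_mut, meta_mut, "elf18")
    dte = te.te_change(te_mut_tab, te_wt_tab)
    inducible = te.call_inducible(counts_wt, meta_wt)

    labels = pd.DataFrame(
        {
            "transcript_id": target_ids + control_ids,
            "group": ["target"] * len(target_ids) + ["control"] * len(control_ids),
        }
    ).merge(inducible[["transcript_id", "inducible"]], on="transcript_id")
    scatter, quadrants = compare.stability_te_scatter(dhalf, dte, labels)
    tgt = scatter[scatter["group"] == "target"]
    frac = (
        ((tgt["log2_halflife_change"] > 0) & (tgt["log2_te_change"] < 0)).mean()
        if len(tgt)
        else 0.0
    )

    merged = dhalf.merge(dte, on="transcript_id").merge(labels, on="transcript_id")
    t_mask = merged["group"] == "target"
    p_half = compare.mann_whitney(
        merged.loc[t_mask, "log2_halflife_change"],
        merged.loc[~t_mask, "log2_halflife_change"],
        metric="halflife_change", group_a="target", group_b="control",
    ).p
    p_te = compare.mann_whitney(
        merged.loc[t_mask, "log2_te_change"],
        merged.loc[~t_mask, "log2_te_change"],
        metric="te_change", group_a="target", group_b="control",
    ).p
    return {
        "stabilized_down_fraction": float(frac),
        "p_halflife_shift": float(p_half),
        "p_te_shift": float(p_te),
        "n_inducible_targets": int(len(tgt)),
        "quadrants": quadrants,
    }
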