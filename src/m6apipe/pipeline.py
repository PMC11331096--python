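"""End-to-end pipeline runs: simulate, call, fit, compare, with provenance.

A :class:`RunConfig` holds every threshold and window parameter (the
defaults mirror the analysis constants: 100/50 nt m6A windows, POM > 3,
POI > 3, 2-of-3 replicates, CLIP step 10, 90th-percentile floor,
Z > 2.576, FDR < 0.05, sigma^2 < 0.0625, t1/2 < 720 min, FC > 1.5,
alpha = 0.05) and round-trips losslessly through YAML.
:func:`run_pipeline` executes one scenario into a run directory and
writes a manifest with the package version, seed, config hash and a
checksum of every output file, so identical configs reproduce identical
manifests.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .annotation import motif_enrichment, segment_distribution
from .clip import call_clip_sites
from .decay import fit_decay_cohort, halflife_change
from .m6a import call_m6a_peaks, classify_condition_specificity
from .simulate import (
    generate_transcriptome,
    plant_peaks,
    simulate_decay_timecourse,
    simulate_ip_input_coverage,
    simulate_polysome_pairs,
    truth_to_frame,
)
from .te import call_inducible, compute_te

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the analysis constants."""

    seed: int = 0
    scenario: str = "m6a"  # m6a | clip | decay | te
    n_transcripts: int = 200
    length_range: tuple[int, int] = (300, 2000)
    depth: float = 100.0
    n_replicates: int = 3
    # m6a windows
    window_length: int = 100
    step: int = 50
    pom_threshold: float = 3.0
    poi_threshold: float = 3.0
    min_replicates: int = 2
    # clip
    clip_window_length: int = 30
    clip_step: int = 10
    z_threshold: float = 2.576
    fdr_threshold: float = 0.05
    control_percentile: float = 90.0
    # peaks
    peak_rate: float = 1.0
    gamma: float = 8.0
    motif: str = "RRACH"
    stop_bias: float = 0.8
    peak_width: int = 150
    # decay
    genotypes: tuple[str, ...] = ("WT", "fip37", "ect234")
    timepoints: tuple[float, ...] = (0, 60, 120, 240)
    noise_cv: float = 0.1
    sigma2_max: float = 0.0625
    halflife_max: float = 720.0
    # te / induction
    fc_threshold: float = 1.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("pom_threshold", "poi_threshold", "z_threshold", "fdr_threshold",
                     "fc_threshold", "alpha", "sigma2_max", "halflife_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in data.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _scenario_m6a(cfg: RunConfig, outdir: str, rng) -> list[str]:
    models, seqs = generate_transcriptome(cfg.n_transcripts, cfg.length_range, seed=rng)
    files = []
    truths, peak_tables = {}, {}
    windows_by_cond = {}
    expression = None
    for cond in ("mock", "elf18"):
        truth, seqs = plant_peaks(
            models, seqs, cfg.peak_rate, cfg.motif, cfg.stop_bias,
            cfg.peak_width, cfg.gamma, seed=rng,
        )
        truths[cond] = truth
        windows, expression = simulate_ip_input_coverage(
            models, truth, cfg.depth, cfg.n_replicates, cfg.window_length,
            cfg.step, expression=expression, seed=rng,
        )
        windows_by_cond[cond] = windows
        ip = [f"ip_rep{r}" for r in range(1, cfg.n_replicates + 1)]
        inp = [f"input_rep{r}" for r in range(1, cfg.n_replicates + 1)]
        peak_tables[cond] = call_m6a_peaks(
            windows, ip, inp, cfg.pom_threshold, cfg.poi_threshold, cfg.min_replicates
        )
        for name, frame in (
            (f"windows_{cond}.tsv", windows),
            (f"truth_{cond}.tsv", truth_to_frame(truth)),
        ):
            io.write_tsv(frame, os.path.join(outdir, name))
            files.append(name)
    labeled_a, labeled_b = classify_condition_specificity(
        peak_tables["mock"], peak_tables["elf18"], windows_by_cond["mock"],
        label_a="mock_specific", label_b="elf18_specific",
    )
    model_map = {m.transcript_id: m for m in models}
    for cond, table in (("mock", labeled_a), ("elf18", labeled_b)):
        io.write_tsv(table, os.path.join(outdir, f"peaks_{cond}.tsv"))
        io.write_bed6(table, os.path.join(outdir, f"peaks_{cond}.bed"))
        files += [f"peaks_{cond}.tsv", f"peaks_{cond}.bed"]
        dist = segment_distribution(table, model_map)
        io.write_tsv(
            dist.rename("fraction").rename_axis("segment").reset_index(),
            os.path.join(outdir, f"metagene_{cond}.tsv"),
        )
        files.append(f"metagene_{cond}.tsv")
    peak_seqs = [
        seqs[row.transcript_id][int(row.start): int(row.end)]
        for row in labeled_a.itertuples(index=False)
    ]
    if peak_seqs:
        enr = motif_enrichment(peak_seqs, cfg.motif, seed=rng, n_randomizations=199)
        io.write_tsv(
            pd.DataFrame([dataclasses.asdict(enr)]), os.path.join(outdir, "motif_mock.tsv")
        )
        files.append("motif_mock.tsv")
    io.write_gff3(models, os.path.join(outdir, "transcripts.gff3"))
    io.write_fasta(seqs, os.path.join(outdir, "transcripts.fasta"))
    files += ["transcripts.gff3", "transcripts.fasta"]
    return files


def _scenario_clip(cfg: RunConfig, outdir: str, rng) -> list[str]:
    models, seqs = generate_transcriptome(cfg.n_transcripts, cfg.length_range, seed=rng)
    truth, seqs = plant_peaks(
        models, seqs, cfg.peak_rate, "UGUA", cfg.stop_bias, 50,
        max(cfg.gamma, 10.0), seed=rng,
    )
    windows, _ = simulate_ip_input_coverage(
        models, truth, max(cfg.depth, 200.0), 2, cfg.clip_window_length,
        cfg.clip_step, control=True, n_control=2, seed=rng,
    )
    sites, stats = call_clip_sites(
        windows, ["ip_rep1", "ip_rep2"], ["input_rep1", "input_rep2"],
        ["control_rep1", "control_rep2"], cfg.z_threshold, cfg.fdr_threshold,
        cfg.control_percentile,
    )
    io.write_tsv(windows, os.path.join(outdir, "windows.tsv"))
    io.write_tsv(truth_to_frame(truth), os.path.join(outdir, "truth.tsv"))
    io.write_tsv(sites, os.path.join(outdir, "sites.tsv"))
    io.write_bed6(sites, os.path.join(outdir, "sites.bed"))
    with open(os.path.join(outdir, "clip_stats.json"), "w") as fh:
        json.dump(dataclasses.asdict(stats), fh, indent=1)
    io.write_gff3(models, os.path.join(outdir, "transcripts.gff3"))
    io.write_fasta(seqs, os.path.join(outdir, "transcripts.fasta"))
    return ["windows.tsv", "truth.tsv", "sites.tsv", "sites.bed", "clip_stats.json",
            "transcripts.gff3", "transcripts.fasta"]


def _scenario_decay(cfg: RunConfig, outdir: str, rng) -> list[str]:
    from .simulate import SyntheticTruth

    halflives = np.exp(rng.uniform(np.log(30), np.log(480), size=cfg.n_transcripts))
    truth = {}
    for i, h in enumerate(halflives):
        tid = f"T{i:05d}"
        alpha = float(np.log(2) / h)
        truth[tid] = SyntheticTruth(
            tid,
            alpha_true={g: alpha for g in cfg.genotypes},
            beta_true={g: 0.0 for g in cfg.genotypes},
        )
    counts, meta = simulate_decay_timecourse(
        truth, cfg.genotypes, cfg.timepoints, cfg.n_replicates,
        max(cfg.depth, 500.0), cfg.noise_cv, seed=rng,
    )
    fits = fit_decay_cohort(counts, meta, seed=int(rng.integers(2**31)))
    files = []
    for name, frame in (
        ("decay_counts.tsv", counts.reset_index()),
        ("decay_metadata.tsv", meta),
        ("decay_fits.tsv", fits),
        ("decay_truth.tsv", truth_to_frame(truth)),
    ):
        io.write_tsv(frame, os.path.join(outdir, name))
        files.append(name)
    if len(cfg.genotypes) > 1 and len(fits):
        dh = halflife_change(fits, cfg.genotypes[1], cfg.genotypes[0])
        io.write_tsv(dh, os.path.join(outdir, "halflife_change.tsv"))
        files.append("halflife_change.tsv")
    return files


def _scenario_te(cfg: RunConfig, outdir: str, rng) -> list[str]:
    from .simulate import SyntheticTruth

    te_true = np.exp(rng.uniform(np.log(0.25), np.log(4), size=cfg.n_transcripts))
    induced = rng.random(cfg.n_transcripts) < 0.2
    fcs = np.where(induced, np.exp(rng.uniform(np.log(2), np.log(6), size=cfg.n_transcripts)), 1.0)
    truth = {
        f"T{i:05d}": SyntheticTruth(
            f"T{i:05d}",
            te_true={"mock": float(v), "elf18": float(v)},
            induction_fc_true=float(fc),
        )
        for i, (v, fc) in enumerate(zip(te_true, fcs))
    }
    counts, meta = simulate_polysome_pairs(
        truth, n_replicates=cfg.n_replicates, depth=max(cfg.depth, 500.0), seed=rng
    )
    te_mock = compute_te(counts, meta, "mock")
    te_elf = compute_te(counts, meta, "elf18")
    inducible = call_inducible(counts, meta, cfg.fc_threshold, cfg.alpha)
    files = []
    for name, frame in (
        ("te_counts.tsv", counts.reset_index()),
        ("te_metadata.tsv", meta),
        ("te_mock.tsv", te_mock),
        ("te_elf18.tsv", te_elf),
        ("inducible.tsv", inducible),
        ("te_truth.tsv", truth_to_frame(truth)),
    ):
        io.write_tsv(frame, os.path.join(outdir, name))
        files.append(name)
    return files


_SCENARIOS = {
    "m6a": _scenario_m6a,
    "clip": _scenario_clip,
    "decay": _scenario_decay,
    "te": _scenario_te,
}


def run_pipeline(config: RunConfig, outdir: str) -> dict[str, Any]:
    """Run one scenario into ``outdir`` and write a provenance manifest."""
    if config.scenario not in _SCENARIOS:
        raise ValueError(
            f"unknown scenario {config.scenario!r}; choose from {sorted(_SCENARIOS)}"
        )
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    try:
        files = _SCENARIOS[config.scenario](config, outdir, rng)
    except Exception:
        with open(os.path.join(outdir, "FAILED"), "w") as fh:
            fh.write("pipeline stage failed; partial outputs retained\n")
        raise
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    files.append("config.yaml")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "scenario": config.scenario,
        "config_hash": config.config_hash(),
        "files": {f: _checksum(os.path.join(outdir, f)) for f in sorted(files)},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
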