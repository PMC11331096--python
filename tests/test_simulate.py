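"""Synthetic-data generators: determinism, structure and calibration."""
import numpy as np
import pandas as pd
import pytest

from m6apipe.simulate import (
    IUPAC,
    PlantedPeak,
    SyntheticTruth,
    generate_transcriptome,
    plant_peaks,
    simulate_decay_timecourse,
    simulate_ip_input_coverage,
    simulate_polysome_pairs,
    truth_from_frame,
    truth_to_frame,
)


def _matches(seq: str, motif: str) -> bool:
    return all(base in IUPAC[m] for base, m in zip(seq, motif))


class TestTranscriptome:
    def test_deterministic_under_seed(self):
        a = generate_transcriptome(5, (1000, 1000), seed=7)
        b = generate_transcriptome(5, (1000, 1000), seed=7)
        assert [m.transcript_id for m in a[0]] == [m.transcript_id for m in b[0]]
        assert a[1] == b[1]
        assert all(m.spliced_length == 1000 for m in a[0])

    def test_structure(self):
        models, seqs = generate_transcriptome(10, (300, 2000), seed=1)
        assert len(models) == 10
        for m in models:
            assert m.cds_length % 3 == 0
            assert m.cds_length >= 150
            assert m.cds_start >= 50 and m.spliced_length - m.cds_end >= 50
            assert set(seqs[m.transcript_id]) <= set("ACGU")

    def test_bad_requests(self):
        with pytest.raises(ValueError):
            generate_transcriptome(0, (300, 2000))
        with pytest.raises(ValueError):
            generate_transcriptome(1, (200, 2000))


class TestPlantPeaks:
    def test_stop_bias_one_centers_all_peaks_at_stop(self):
        models, seqs = generate_transcriptome(30, (600, 2000), seed=2)
        truth, _ = plant_peaks(models, seqs, peak_rate=1.0, stop_bias=1.0, seed=2)
        by_id = {m.transcript_id: m for m in models}
        n = 0
        for tid, t in truth.items():
            for p in t.planted_peaks:
                assert abs(p.center - by_id[tid].stop_codon_start) <= 50 + 1
                n += 1
        assert n > 0

    def test_motif_written_at_center(self):
        models, seqs = generate_transcriptome(20, (500, 1500), seed=3)
        truth, edited = plant_peaks(models, seqs, peak_rate=1.0, motif="RRACH", seed=3)
        for tid, t in truth.items():
            for p in t.planted_peaks:
                start = p.center - len(p.motif) // 2
                written = edited[tid][start : start + len(p.motif)]
                assert written == p.motif
                assert _matches(written, "RRACH")

    def test_zero_rate_and_invalid_motif(self):
        models, seqs = generate_transcriptome(3, (300, 500), seed=0)
        truth, _ = plant_peaks(models, seqs, peak_rate=0.0, seed=0)
        assert all(not t.planted_peaks for t in truth.values())
        with pytest.raises(ValueError):
            plant_peaks(models, seqs, motif="RRXCH")
        with pytest.raises(ValueError):
            plant_peaks(models, seqs, stop_bias=1.5)

    def test_truth_invariants_enforced(self):
        with pytest.raises(ValueError):
            PlantedPeak(0, 100, 0.5, "GGACU")
        with pytest.raises(ValueError):
            SyntheticTruth("x", alpha_true={"WT": -1.0})


class TestIpInputCoverage:
    def test_control_matches_input_on_average(self):
        """gamma = 1 control: mean IP/input ratio within 10% of 1."""
        models, seqs = generate_transcriptome(400, (1000, 2000), seed=4)
        truth = {m.transcript_id: SyntheticTruth(m.transcript_id) for m in models}
        table, _ = simulate_ip_input_coverage(
            models, truth, depth=200, n_replicates=1, control=True, n_control=1, seed=4
        )
        assert len(table) >= 10_000
        ratio = (table["control_rep1"] + 1) / (table["input_rep1"] + 1)
        assert 0.9 < ratio.mean() < 1.1

    def test_poisson_in_peak_mean(self):
        """Fully covered peak windows average depth*gamma*expression."""
        from m6apipe.coverage import TranscriptModel

        model = TranscriptModel("T1.1", 1000, 100, 700)
        truth = {"T1.1": SyntheticTruth("T1.1", planted_peaks=[PlantedPeak(400, 600, 8.0, "GGACU")])}
        table, _ = simulate_ip_input_coverage(
            [model], truth, depth=100, n_replicates=200, noise_model="poisson",
            expression={"T1.1": 1.0}, seed=5,
        )
        inside = table[(table["window_start"] >= 400) & (table["window_end"] <= 600)]
        ip_cols = [c for c in table.columns if c.startswith("ip_")]
        counts = inside[ip_cols].to_numpy().ravel()
        se = np.sqrt(800 / len(counts))
        assert abs(counts.mean() - 800) < 3 * se

    def test_depth_zero_rejected(self):
        models, seqs = generate_transcriptome(1, (300, 300), seed=0)
        truth = {m.transcript_id: SyntheticTruth(m.transcript_id) for m in models}
        with pytest.raises(ValueError):
            simulate_ip_input_coverage(models, truth, depth=0)

    def test_deterministic(self):
        models, _ = generate_transcriptome(5, (300, 800), seed=6)
        truth = {m.transcript_id: SyntheticTruth(m.transcript_id) for m in models}
        t1, _ = simulate_ip_input_coverage(models, truth, depth=50, seed=9)
        t2, _ = simulate_ip_input_coverage(models, truth, depth=50, seed=9)
        pd.testing.assert_frame_equal(t1, t2)


class TestDecayTimecourse:
    @pytest.fixture
    def truth(self):
        return {
            f"T{i}": SyntheticTruth(f"T{i}", alpha_true={"WT": 0.005}, beta_true={"WT": 0.0})
            for i in range(10)
        }

    def test_shapes_and_metadata(self, truth):
        counts, meta = simulate_decay_timecourse(truth, ["WT"], seed=1)
        assert counts.shape[1] == 12  # 4 timepoints x 3 replicates
        assert len(counts) == 10 + 50  # transcripts + spike-ins
        assert set(meta.columns) >= {"library", "genotype", "timepoint_min", "replicate",
                                     "size_factor"}
        assert ((meta["size_factor"] >= 0.5) & (meta["size_factor"] <= 2.0)).all()

    def test_timepoint_validation(self, truth):
        with pytest.raises(ValueError):
            simulate_decay_timecourse(truth, ["WT"], timepoints=(0, -10))
        with pytest.raises(ValueError):
            simulate_decay_timecourse(truth, ["WT"], timepoints=(60, 120))

    def test_spikeins_are_stable(self, truth):
        """Spike-in rows track size factors, not the decay profile."""
        counts, meta = simulate_decay_timecourse(truth, ["WT"], depth=2000,
                                                 noise_cv=0.01, seed=2)
        spikes = counts.loc[[i for i in counts.index if i.startswith("SPIKE")]]
        norm = spikes.to_numpy() / meta["size_factor"].to_numpy()
        t = meta["timepoint_min"].to_numpy()
        late = norm[:, t == 240].mean()
        early = norm[:, t == 0].mean()
        assert late / early == pytest.approx(1.0, rel=0.05)


class TestPolysomePairs:
    def test_library_layout(self):
        truth = {f"T{i}": SyntheticTruth(f"T{i}", te_true={"mock": 1.0, "elf18": 1.0})
                 for i in range(5)}
        counts, meta = simulate_polysome_pairs(truth, n_replicates=3, seed=1)
        for cond in ("mock", "elf18"):
            sub = meta[meta["condition"] == cond]
            assert (sub["fraction"] == "input").sum() == 3
            assert (sub["fraction"] == "polysome").sum() == 3

    def test_induction_fold_change_recovered(self):
        """Input elf18/mock ratio approximates the planted fold-change."""
        truth = {f"T{i}": SyntheticTruth(f"T{i}", te_true={"mock": 1.0, "elf18": 1.0},
                                         induction_fc_true=2.0)
                 for i in range(400)}
        counts, meta = simulate_polysome_pairs(truth, depth=1000, seed=3)
        inputs = meta[meta["fraction"] == "input"]

        def level(cond):
            sub = inputs[inputs["condition"] == cond]
            norm = counts[sub["library"]].to_numpy() / sub["size_factor"].to_numpy()
            return norm.mean()

        assert level("elf18") / level("mock") == pytest.approx(2.0, rel=0.05)


class TestTruthRoundTrip:
    def test_frame_round_trip(self, tmp_path):
        models, seqs = generate_transcriptome(5, (400, 900), seed=8)
        truth, _ = plant_peaks(models, seqs, peak_rate=1.0, seed=8)
        for i, t in enumerate(truth.values()):
            t.alpha_true = {"WT": 0.01 + i * 1e-3, "fip37": 0.005}
            t.beta_true = {"WT": 0.0, "fip37": 0.001}
            t.te_true = {"mock": 1.5}
            t.induction_fc_true = 2.5
        frame = truth_to_frame(truth)
        path = tmp_path / "truth.tsv"
        frame.to_csv(path, sep="\t", index=False)
        back = truth_from_frame(pd.read_csv(path, sep="\t"))
        assert back == truth
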