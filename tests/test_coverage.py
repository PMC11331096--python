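"""Window grids, median normalization, POI scores and annotation import."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6apipe.coverage import (
    TranscriptModel,
    make_window_grid,
    normalize_windows,
    poi_scores,
    select_longest_isoform,
    window_table,
)


class TestWindowGrid:
    @pytest.mark.parametrize(
        "length,window,step,expected",
        [
            (250, 100, 50, [(0, 100), (50, 150), (100, 200), (150, 250)]),
            (100, 100, 50, [(0, 100)]),
            (300, 100, 100, [(0, 100), (100, 200), (200, 300)]),
            (80, 100, 50, [(0, 80)]),  # window longer than transcript
        ],
    )
    def test_examples(self, length, window, step, expected):
        grid = make_window_grid(length, window, step, "t")
        assert [tuple(w) for w in grid.windows] == expected

    def test_zero_step_rejected(self):
        with pytest.raises(ValueError):
            make_window_grid(200, 100, 0)

    @given(
        length=st.integers(101, 5000),
        step=st.integers(1, 100),
        mult=st.integers(1, 5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_tiling_invariants(self, length, step, mult):
        """Grids tile the transcript; starts advance by exactly `step`."""
        window = step * mult
        if window > length:
            window = length
        grid = make_window_grid(length, window, step, "t")
        w = grid.windows
        assert w[0, 0] == 0
        assert w[-1, 1] == length
        assert np.all(np.diff(w[:, 0]) == step)
        assert np.all(w[:, 1] - w[:, 0] >= min(step, length))
        # every position covered
        assert np.all(w[1:, 0] <= w[:-1, 1])

    def test_clip_grid_arithmetic(self):
        grid = make_window_grid(300, 100, 10, "t")
        assert list(grid.starts[:3]) == [0, 10, 20]
        assert grid.windows[-1, 1] == 300


class TestNormalization:
    def test_hand_example(self):
        norm = normalize_windows([2, 4, 6, 100], pseudocount=1)
        assert norm == pytest.approx([0.5, 0.8333, 1.1667, 16.8333], abs=1e-4)

    def test_constant_coverage_is_identity(self):
        assert normalize_windows([7, 7, 7]) == pytest.approx([1, 1, 1])

    def test_all_zero_library(self):
        assert normalize_windows([0, 0, 0], 1) == pytest.approx([1, 1, 1])

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            normalize_windows([], 1)
        with pytest.raises(ValueError):
            normalize_windows([1, 2], 0)

    @given(st.lists(st.integers(0, 10_000), min_size=3, max_size=51))
    @settings(max_examples=100, derandomize=True)
    def test_median_of_norm_is_one_for_odd_counts(self, raw):
        if len(raw) % 2 == 0:
            raw = raw + [raw[0]]
        assert np.median(normalize_windows(raw)) == pytest.approx(1.0)


class TestPoi:
    def test_identity_and_division(self):
        assert poi_scores([4.0], [1.25])[0] == pytest.approx(3.2)
        same = np.array([0.5, 1.0, 2.0])
        assert poi_scores(same, same) == pytest.approx([1, 1, 1])

    def test_linearity(self):
        inp = np.array([1.0, 2.0])
        assert poi_scores(2 * inp, inp) == pytest.approx(2 * poi_scores(inp, inp))

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            poi_scores([1.0, 2.0], [1.0])

    def test_depth_scale_invariance_at_vanishing_pseudocount(self):
        """Scaling raw counts with the pseudocount leaves POI unchanged."""
        rng = np.random.default_rng(1)
        raw_ip = rng.integers(1, 500, size=31).astype(float)
        raw_in = rng.integers(1, 500, size=31).astype(float)
        eps = 1e-9
        poi = poi_scores(normalize_windows(raw_ip, eps), normalize_windows(raw_in, eps))
        poi_scaled = poi_scores(
            normalize_windows(10 * raw_ip, 10 * eps), normalize_windows(raw_in, eps)
        )
        assert poi_scaled == pytest.approx(poi)


GFF = """##gff-version 3
chr1\ttest\tgene\t1\t5000\t.\t+\t.\tID=AT1G01010
chr1\ttest\tmRNA\t1\t3000\t.\t+\t.\tID=AT1G01010.1;Parent=AT1G01010
chr1\ttest\texon\t1\t1000\t.\t+\t.\tParent=AT1G01010.1
chr1\ttest\tCDS\t101\t700\t.\t+\t0\tParent=AT1G01010.1
chr1\ttest\tmRNA\t1\t5000\t.\t+\t.\tID=AT1G01010.2;Parent=AT1G01010
chr1\ttest\texon\t1\t700\t.\t+\t.\tParent=AT1G01010.2
chr1\ttest\texon\t1001\t1500\t.\t+\t.\tParent=AT1G01010.2
chr1\ttest\tCDS\t101\t700\t.\t+\t0\tParent=AT1G01010.2
chr1\ttest\tCDS\t1001\t1300\t.\t+\t0\tParent=AT1G01010.2
chr2\ttest\tgene\t1\t2000\t.\t-\t.\tID=AT2G02020
chr2\ttest\tmRNA\t1\t2000\t.\t-\t.\tID=AT2G02020.1;Parent=AT2G02020
chr2\ttest\texon\t1\t900\t.\t-\t.\tParent=AT2G02020.1
chr2\ttest\texon\t1201\t2000\t.\t-\t.\tParent=AT2G02020.1
chr2\ttest\tCDS\t301\t900\t.\t-\t0\tParent=AT2G02020.1
chr2\ttest\tCDS\t1201\t1500\t.\t-\t0\tParent=AT2G02020.1
chr3\ttest\tgene\t1\t500\t.\t+\t.\tID=AT3G03030
chr3\ttest\tmRNA\t1\t500\t.\t+\t.\tID=AT3G03030.1;Parent=AT3G03030
chr3\ttest\texon\t1\t500\t.\t+\t.\tParent=AT3G03030.1
"""

TIE_GFF = """##gff-version 3
chr1\ttest\tgene\t1\t2000\t.\t+\t.\tID=G1
chr1\ttest\tmRNA\t1\t1000\t.\t+\t.\tID=G1.2;Parent=G1
chr1\ttest\texon\t1\t1000\t.\t+\t.\tParent=G1.2
chr1\ttest\tCDS\t101\t700\t.\t+\t0\tParent=G1.2
chr1\ttest\tmRNA\t1001\t2000\t.\t+\t.\tID=G1.1;Parent=G1
chr1\ttest\texon\t1001\t2000\t.\t+\t.\tParent=G1.1
chr1\ttest\tCDS\t1101\t1700\t.\t+\t0\tParent=G1.1
"""


class TestLongestIsoform:
    def test_longest_wins_and_no_cds_excluded(self, tmp_path):
        path = tmp_path / "test.gff3"
        path.write_text(GFF)
        models = {m.gene_id: m for m in select_longest_isoform(str(path))}
        # AT1G01010: isoform .2 spliced length 1200 beats .1 (1000)
        assert models["AT1G01010"].transcript_id == "AT1G01010.2"
        assert models["AT1G01010"].spliced_length == 1200
        # CDS in transcript coordinates: 100 nt leader, 600+300 nt CDS
        assert models["AT1G01010"].cds_start == 100
        assert models["AT1G01010"].cds_end == 1000
        # no-CDS gene absent
        assert "AT3G03030" not in models

    def test_minus_strand_coordinates(self, tmp_path):
        path = tmp_path / "test.gff3"
        path.write_text(GFF)
        models = {m.gene_id: m for m in select_longest_isoform(str(path))}
        m = models["AT2G02020"]
        # transcript runs 2000 -> 1201 then 900 -> 1; CDS starts at
        # genomic 1500 = transcript position 500, total CDS 600+300
        assert m.spliced_length == 1700
        assert m.cds_start == 500
        assert m.cds_end == 1400

    def test_tie_broken_by_smallest_id(self, tmp_path):
        path = tmp_path / "tie.gff3"
        path.write_text(TIE_GFF)
        (model,) = select_longest_isoform(str(path))
        assert model.transcript_id == "G1.1"


class TestTranscriptModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            TranscriptModel("x", 100, 50, 40)  # start >= end
        with pytest.raises(ValueError):
            TranscriptModel("x", 100, 10, 60)  # CDS length 50 not %3

    def test_window_table_sorted(self, toy_model):
        other = TranscriptModel("AAA.1", 400, 100, 250)
        table = window_table([toy_model, other], 100, 50)
        assert list(table["transcript_id"].unique()) == ["AAA.1", "TOY.1"]
        assert table.groupby("transcript_id")["window_start"].is_monotonic_increasing.all()
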