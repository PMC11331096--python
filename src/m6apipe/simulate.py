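"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the library structure of the study designs this
package analyses, without simulating reads:

* a transcriptome of single-isoform transcript models (5' leader, CDS,
  3' UTR) with random sequences over {A, C, G, U};
* m6A-IP / FA-CLIP style window-count tables: an input library follows
  the transcript's expression level, the IP library is enriched by a
  factor ``gamma`` inside planted peaks and depleted to a background
  efficiency ``LAMBDA_BG`` outside them, and a non-specific (YFP-like)
  control IP tracks the input everywhere (``gamma = 1``);
* decay time courses following m(t) = exp(-(alpha/beta)(1 - e^(-beta t)))
  (simple exponential when beta = 0), with multiplicative noise and
  library-specific size factors;
* paired polysome/input counts with per-transcript translation
  efficiency and elf18-inducible input fold-changes.

Planted peaks are centred on an exact instance of a consensus motif
(RRACH for m6A, UGUA for the CLIP scenario) written into the sequence,
with a configurable bias towards the stop codon.

Every generator is deterministic under a fixed seed.
"""
from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .coverage import TranscriptModel, window_table

__all__ = [
    "LAMBDA_BG",
    "PlantedPeak",
    "SyntheticTruth",
    "generate_transcriptome",
    "plant_peaks",
    "simulate_ip_input_coverage",
    "simulate_decay_timecourse",
    "simulate_polysome_pairs",
    "draw_expression",
    "truth_to_frame",
    "truth_from_frame",
]

#: IP efficiency for unmodified RNA relative to input (the IP step
#: depletes unmodified fragments); windows outside planted peaks have
#: expected IP coverage ``LAMBDA_BG * expression * depth``.
LAMBDA_BG = 0.5

#: Negative-binomial dispersion of simulated counts (var = mu + d*mu^2).
NB_DISPERSION = 0.05

#: Expression levels are log-normal(log EXPRESSION_SCALE, 1) and divided
#: by EXPRESSION_SCALE so the median relative expression is ~1.
EXPRESSION_SCALE = 50.0

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


@dataclasses.dataclass(frozen=True)
class PlantedPeak:
    """One planted enrichment peak, in transcript coordinates."""

    start: int
    end: int
    gamma: float
    motif: str  # the exact motif instance written at the peak centre

    def __post_init__(self) -> None:
        if self.gamma < 1:
            raise ValueError("enrichment factor gamma must be >= 1")
        if self.start >= self.end:
            raise ValueError("empty peak interval")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth for one synthetic transcript.

    ``alpha_true``/``beta_true`` map genotype -> decay parameters
    (min^-1), ``te_true`` maps condition -> translation-efficiency
    ratio, ``induction_fc_true`` is the elf18/mock input fold-change.
    """

    transcript_id: str
    planted_peaks: list[PlantedPeak] = dataclasses.field(default_factory=list)
    alpha_true: dict[str, float] = dataclasses.field(default_factory=dict)
    beta_true: dict[str, float] = dataclasses.field(default_factory=dict)
    te_true: dict[str, float] = dataclasses.field(default_factory=dict)
    induction_fc_true: float = 1.0

    def __post_init__(self) -> None:
        for a in self.alpha_true.values():
            if a <= 0:
                raise ValueError("alpha_true must be > 0")
        for b in self.beta_true.values():
            if b < 0:
                raise ValueError("beta_true must be >= 0")
        for te in self.te_true.values():
            if te <= 0:
                raise ValueError("te_true must be > 0")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def draw_expression(n: int, rng: np.random.Generator) -> np.ndarray:
    """Relative expression levels (median ~ 1), log-normal with sigma=1."""
    return rng.lognormal(mean=np.log(EXPRESSION_SCALE), sigma=1.0, size=n) / EXPRESSION_SCALE


def _sample_counts(
    mean: np.ndarray,
    rng: np.random.Generator,
    noise_model: str = "nb",
    dispersion: float = NB_DISPERSION,
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if noise_model == "poisson":
        return rng.poisson(mean)
    if noise_model == "nb":
        if dispersion <= 0:
            return rng.poisson(mean)
        n = 1.0 / dispersion
        p = n / (n + np.maximum(mean, 1e-12))
        return rng.negative_binomial(n, p)
    raise ValueError(f"unknown noise model {noise_model!r}")


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def generate_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int] = (300, 2000),
    seed: int | np.random.Generator = 0,
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """Generate transcript models and random {A,C,G,U} sequences.

    Each transcript has a 5' leader of at least 50 nt, a CDS of at least
    150 nt (a multiple of 3, ending in a stop codon position) and a
    3' UTR of at least 50 nt, so transcripts must be >= 300 nt.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 300:
        raise ValueError(
            "minimum transcript length is 300 nt (50 nt leader + 150 nt CDS "
            "+ 50 nt UTR with margins)"
        )
    if hi < lo:
        raise ValueError("empty length range")
    rng = _rng(seed)
    models: list[TranscriptModel] = []
    sequences: dict[str, str] = {}
    for i in range(n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        # leader and UTR each take >= 50 nt; CDS gets the rest, >= 150 nt
        spare = length - 300
        leader = 50 + int(rng.integers(0, spare // 3 + 1))
        utr = 50 + int(rng.integers(0, spare // 3 + 1))
        cds_len = length - leader - utr
        cds_len -= cds_len % 3
        utr = length - leader - cds_len
        tid = f"SYNT{i + 1:05d}.1"
        models.append(
            TranscriptModel(
                transcript_id=tid,
                spliced_length=length,
                cds_start=leader,
                cds_end=leader + cds_len,
                gene_id=f"SYNT{i + 1:05d}",
            )
        )
        sequences[tid] = "".join(rng.choice(list("ACGU"), size=length))
    return models, sequences


# ---------------------------------------------------------------------------
# Peak planting
# ---------------------------------------------------------------------------

def _expand_iupac(motif: str, rng: np.random.Generator) -> str:
    try:
        return "".join(rng.choice(list(IUPAC[c])) for c in motif.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter in motif {motif!r}: {exc}") from exc


def plant_peaks(
    models: Sequence[TranscriptModel],
    sequences: dict[str, str],
    peak_rate: float = 1.0,
    motif: str = "RRACH",
    stop_bias: float = 0.8,
    peak_width: int = 150,
    gamma: float | tuple[float, float] = 8.0,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, SyntheticTruth], dict[str, str]]:
    """Plant enrichment peaks centred on exact motif instances.

    The number of peaks per transcript is Poisson(``peak_rate``).  With
    probability ``stop_bias`` a peak centre falls within the stop codon
    +/- 50 nt, otherwise uniformly on the transcript.  The motif (IUPAC)
    is concretized and written into the sequence at the peak centre;
    peak intervals are clipped to the transcript.  Returns per-transcript
    truth and the edited sequences; peaks that cannot be placed (motif
    longer than the transcript, or no non-overlapping slot found) are
    skipped and counted on ``plant_peaks.skipped``.
    """
    if not (0.0 <= stop_bias <= 1.0):
        raise ValueError("stop_bias must be in [0, 1]")
    for c in motif.upper():
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {c!r} in motif")
    rng = _rng(seed)
    truth: dict[str, SyntheticTruth] = {}
    out_seqs = dict(sequences)
    skipped = 0
    for model in models:
        tid = model.transcript_id
        seq = list(out_seqs[tid])
        length = model.spliced_length
        peaks: list[PlantedPeak] = []
        n_peaks = rng.poisson(peak_rate) if peak_rate > 0 else 0
        for _ in range(n_peaks):
            if len(motif) > length:
                skipped += 1
                continue
            placed = False
            for _attempt in range(10):
                if rng.random() < stop_bias:
                    center = int(
                        rng.integers(
                            max(0, model.stop_codon_start - 50),
                            min(length, model.stop_codon_start + 51),
                        )
                    )
                else:
                    center = int(rng.integers(0, length))
                start = max(0, center - peak_width // 2)
                end = min(length, start + peak_width)
                start = max(0, end - peak_width)
                # the motif instance sits at the midpoint of the (possibly
                # clipped) peak interval
                center = (start + end) // 2
                m_start = center - len(motif) // 2
                if m_start < 0 or m_start + len(motif) > length:
                    continue
                if any(p.start < end and start < p.end for p in peaks):
                    continue
                if isinstance(gamma, tuple):
                    g = float(rng.uniform(*gamma))
                else:
                    g = float(gamma)
                instance = _expand_iupac(motif, rng)
                seq[m_start : m_start + len(motif)] = list(instance)
                peaks.append(PlantedPeak(start=start, end=end, gamma=g, motif=instance))
                placed = True
                break
            if not placed:
                skipped += 1
        out_seqs[tid] = "".join(seq)
        truth[tid] = SyntheticTruth(transcript_id=tid, planted_peaks=sorted(peaks, key=lambda p: p.start))
    plant_peaks.skipped = skipped  # type: ignore[attr-defined]
    return truth, out_seqs


# ---------------------------------------------------------------------------
# IP / input window coverage
# ---------------------------------------------------------------------------

def _window_enrichment(
    starts: np.ndarray, ends: np.ndarray, peaks: list[PlantedPeak], window_length: int
) -> np.ndarray:
    """Expected IP enrichment per window.

    The window rate mixes the enriched rate ``gamma`` over the portion of
    the window inside a peak with the background efficiency ``LAMBDA_BG``
    over the rest, in proportion to overlap length.
    """
    enrich = np.full(starts.shape, LAMBDA_BG, dtype=float)
    width = np.maximum(ends - starts, 1)
    for p in peaks:
        ovl = np.minimum(ends, p.end) - np.maximum(starts, p.start)
        ovl = np.clip(ovl, 0, None) / width
        enrich += ovl * (p.gamma - LAMBDA_BG)
    return enrich


def simulate_ip_input_coverage(
    models: Sequence[TranscriptModel],
    truth: dict[str, SyntheticTruth],
    depth: float = 100.0,
    n_replicates: int = 3,
    window_length: int = 100,
    step: int = 50,
    control: bool = False,
    n_control: int = 2,
    noise_model: str = "nb",
    dispersion: float = NB_DISPERSION,
    expression: dict[str, float] | None = None,
    prefix: str = "",
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate IP/input (and optional control-IP) window-count tables.

    Expected input coverage of a full window is ``depth * expression``;
    IP coverage is multiplied by the planted enrichment ``gamma`` inside
    peaks and by ``LAMBDA_BG`` outside; control-IP libraries have
    ``gamma = 1`` everywhere.  Truncated windows are scaled by their
    length.  Returns a window table with one column per library
    (``{prefix}ip_rep1 ...``, ``{prefix}input_rep1 ...``,
    ``{prefix}control_rep1 ...``) and the per-transcript relative
    expression used.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = _rng(seed)
    if expression is None:
        levels = draw_expression(len(models), rng)
        expression = {m.transcript_id: float(e) for m, e in zip(models, levels)}
    table = window_table(models, window_length, step)
    starts = table["window_start"].to_numpy()
    ends = table["window_end"].to_numpy()
    expr = table["transcript_id"].map(expression).to_numpy(dtype=float)
    len_scale = (ends - starts) / window_length

    enrich = np.full(len(table), LAMBDA_BG, dtype=float)
    for model in models:
        tid = model.transcript_id
        peaks = truth[tid].planted_peaks if tid in truth else []
        mask = table["transcript_id"].to_numpy() == tid
        if peaks:
            enrich[mask] = _window_enrichment(starts[mask], ends[mask], peaks, window_length)
        # transcripts without peaks keep LAMBDA_BG everywhere

    base = depth * expr * len_scale
    cols = {}
    for r in range(1, n_replicates + 1):
        cols[f"{prefix}input_rep{r}"] = _sample_counts(base, rng, noise_model, dispersion)
        cols[f"{prefix}ip_rep{r}"] = _sample_counts(base * enrich, rng, noise_model, dispersion)
    if control:
        for r in range(1, n_control + 1):
            cols[f"{prefix}control_rep{r}"] = _sample_counts(base, rng, noise_model, dispersion)
    return pd.concat([table, pd.DataFrame(cols, index=table.index)], axis=1), expression


# ---------------------------------------------------------------------------
# Decay time courses
# ---------------------------------------------------------------------------

def simulate_decay_timecourse(
    truth: dict[str, SyntheticTruth],
    genotypes: Sequence[str] = ("WT",),
    timepoints: Sequence[float] = (0, 60, 120, 240),
    n_replicates: int = 3,
    depth: float = 500.0,
    noise_cv: float = 0.1,
    n_spikeins: int = 50,
    expression: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a QuantSeq-style decay time course.

    Expected counts are ``depth * expression * m(t) * size_factor`` with
    ``m(t)`` the two-parameter decay curve for the transcript's
    per-genotype (alpha, beta) truth; counts are Poisson draws around a
    log-normal multiplicative noise term with coefficient of variation
    ``noise_cv``.  Size factors are drawn uniformly on [0.5, 2] per
    library to make the normalization stage matter.

    Because transcription is shut off, every transcript decays and a
    global exponential trend is not identifiable from relative counts
    alone; as in real decay assays the libraries therefore carry
    ``n_spikeins`` stable spike-in rows (ids ``SPIKE....``, constant
    expected abundance times the library size factor) that downstream
    normalization can anchor on (see
    :func:`m6apipe.decay.fit_decay_cohort`'s ``control_genes``).

    Returns ``(counts, metadata)``: a gene x library count matrix
    (spike-in rows last) and a library metadata table (genotype,
    timepoint_min, replicate, size_factor).
    """
    from .decay import decay_curve

    timepoints = list(timepoints)
    if any(t < 0 for t in timepoints):
        raise ValueError("negative timepoint")
    if 0 not in timepoints and 0.0 not in timepoints:
        raise ValueError("timepoints must include 0")
    rng = _rng(seed)
    tids = sorted(truth)
    if expression is None:
        levels = draw_expression(len(tids), rng)
        expression = dict(zip(tids, (float(x) for x in levels)))

    libraries = []
    for g in genotypes:
        for t in timepoints:
            for r in range(1, n_replicates + 1):
                libraries.append((f"{g}_t{int(t)}_rep{r}", g, float(t), r))
    size_factors = rng.uniform(0.5, 2.0, size=len(libraries))
    meta = pd.DataFrame(
        [
            {"library": lib, "genotype": g, "timepoint_min": t, "replicate": r,
             "size_factor": sf}
            for (lib, g, t, r), sf in zip(libraries, size_factors)
        ]
    )

    sigma = np.sqrt(np.log1p(noise_cv**2))
    spike_ids = [f"SPIKE{i + 1:04d}" for i in range(n_spikeins)]
    spike_expr = draw_expression(n_spikeins, rng) if n_spikeins else np.empty(0)
    counts = {}
    expr = np.array([expression[tid] for tid in tids])
    for (lib, g, t, _r), sf in zip(libraries, size_factors):
        m = np.array([decay_curve(t, truth[tid].alpha_true[g], truth[tid].beta_true.get(g, 0.0))
                      for tid in tids])
        mean = np.concatenate([depth * expr * m * sf, depth * spike_expr * sf])
        noised = mean * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=len(mean))
        counts[lib] = rng.poisson(noised)
    counts_df = pd.DataFrame(
        counts, index=pd.Index(tids + spike_ids, name="transcript_id")
    )
    return counts_df, meta


# ---------------------------------------------------------------------------
# Polysome / input pairs
# ---------------------------------------------------------------------------

def simulate_polysome_pairs(
    truth: dict[str, SyntheticTruth],
    conditions: Sequence[str] = ("mock", "elf18"),
    n_replicates: int = 3,
    depth: float = 500.0,
    noise_model: str = "nb",
    dispersion: float = NB_DISPERSION,
    expression: dict[str, float] | None = None,
    genotype: str = "WT",
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired polysome/input count libraries.

    Expected input counts are ``depth * expression * size_factor``
    (times ``induction_fc_true`` under elf18); expected polysome counts
    are ``te_true`` times the expected input counts under the same
    condition.  Returns ``(counts, metadata)`` with metadata columns
    (library, condition, fraction, replicate, size_factor).
    """
    rng = _rng(seed)
    tids = sorted(truth)
    if expression is None:
        levels = draw_expression(len(tids), rng)
        expression = dict(zip(tids, (float(x) for x in levels)))
    expr = np.array([expression[tid] for tid in tids])
    fc = np.array([truth[tid].induction_fc_true for tid in tids])

    rows, counts = [], {}
    for cond in conditions:
        cond_fc = fc if cond == "elf18" else np.ones_like(fc)
        te = np.array([truth[tid].te_true.get(cond, truth[tid].te_true.get("mock", 1.0))
                       for tid in tids])
        for fraction in ("input", "polysome"):
            for r in range(1, n_replicates + 1):
                lib = f"{genotype}_{cond}_{fraction}_rep{r}"
                sf = float(rng.uniform(0.5, 2.0))
                mean = depth * expr * cond_fc * sf
                if fraction == "polysome":
                    mean = mean * te
                counts[lib] = _sample_counts(mean, rng, noise_model, dispersion)
                rows.append({"library": lib, "genotype": genotype, "condition": cond,
                             "fraction": fraction, "replicate": r, "size_factor": sf})
    counts_df = pd.DataFrame(counts, index=pd.Index(tids, name="transcript_id"))
    return counts_df, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Truth serialization (TSV round-trip)
# ---------------------------------------------------------------------------

def truth_to_frame(truth: dict[str, SyntheticTruth]) -> pd.DataFrame:
    """Flatten truth to a TSV-friendly table (one row per transcript)."""
    rows = []
    for tid in sorted(truth):
        t = truth[tid]
        rows.append(
            {
                "transcript_id": tid,
                "peaks": ";".join(
                    f"{p.start}-{p.end}:{p.gamma:g}:{p.motif}" for p in t.planted_peaks
                ),
                "alpha_true": ";".join(f"{g}={v:.17g}" for g, v in sorted(t.alpha_true.items())),
                "beta_true": ";".join(f"{g}={v:.17g}" for g, v in sorted(t.beta_true.items())),
                "te_true": ";".join(f"{c}={v:.17g}" for c, v in sorted(t.te_true.items())),
                "induction_fc_true": t.induction_fc_true,
            }
        )
    return pd.DataFrame(rows)


def _parse_kv(field: str) -> dict[str, float]:
    if not field:
        return {}
    return {k: float(v) for k, v in (item.split("=") for item in field.split(";"))}


def truth_from_frame(frame: pd.DataFrame) -> dict[str, SyntheticTruth]:
    """Inverse of :func:`truth_to_frame`."""
    truth = {}
    for row in frame.itertuples(index=False):
        peaks = []
        peaks_field = "" if pd.isna(row.peaks) else str(row.peaks)
        if peaks_field:
            for item in peaks_field.split(";"):
                span, g, motif = item.split(":")
                s, e = span.split("-")
                peaks.append(PlantedPeak(int(s), int(e), float(g), motif))
        truth[row.transcript_id] = SyntheticTruth(
            transcript_id=row.transcript_id,
            planted_peaks=peaks,
            alpha_true=_parse_kv("" if pd.isna(row.alpha_true) else str(row.alpha_true)),
            beta_true=_parse_kv("" if pd.isna(row.beta_true) else str(row.beta_true)),
            te_true=_parse_kv("" if pd.isna(row.te_true) else str(row.te_true)),
            induction_fc_true=float(row.induction_fc_true),
        )
    return truth
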