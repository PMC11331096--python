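"""Transcript coordinate frames and sliding-window coverage scores.

Both peak callers in this package (the m6A-IP caller and the FA-CLIP
caller) operate on the same primitives defined here:

* a :class:`TranscriptModel` — the spliced coordinate frame of one gene's
  longest isoform with its CDS landmarks,
* a :class:`WindowGrid` — a sliding window tiling of that frame,
* window scores — raw counts, pseudocounted median-normalized coverage
  (the peak-over-median score, POM) and the IP/input ratio of normalized
  coverage (the peak-over-input score, POI).

All internal coordinates are 0-based half-open; GFF3 input (1-based,
inclusive) is converted on read and BED output is written 0-based
half-open.
"""
from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "WindowGrid",
    "select_longest_isoform",
    "make_window_grid",
    "window_table",
    "normalize_windows",
    "normalize_table",
    "poi_scores",
]


@dataclasses.dataclass(frozen=True)
class TranscriptModel:
    """Exon-spliced coordinate frame of one transcript.

    Parameters
    ----------
    transcript_id : str
        Identifier, e.g. ``AT1G01010.1``.
    spliced_length : int
        Length of the exon-spliced transcript in nucleotides.
    cds_start : int
        Transcript coordinate of the first base of the start codon
        (0-based).
    cds_end : int
        Transcript coordinate one past the last base of the stop codon
        (0-based, half-open); the CDS is taken to include the stop codon.
    gene_id : str, optional
        Parent gene identifier.
    """

    transcript_id: str
    spliced_length: int
    cds_start: int
    cds_end: int
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= self.spliced_length):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript of length {self.spliced_length}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length "
                f"{self.cds_end - self.cds_start} not a multiple of 3"
            )

    @property
    def stop_codon_start(self) -> int:
        """Transcript coordinate of the first base of the stop codon."""
        return self.cds_end - 3

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start


@dataclasses.dataclass(frozen=True)
class WindowGrid:
    """Sliding-window tiling of one transcript.

    ``windows`` is an ``(n, 2)`` integer array of ``[start, end)``
    transcript coordinates.  Consecutive starts differ by exactly
    ``step``; the final window is truncated to the transcript end but is
    always at least ``step`` long, so the grid tiles the full transcript.
    """

    transcript_id: str
    window_length: int
    step: int
    windows: np.ndarray

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def starts(self) -> np.ndarray:
        return self.windows[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.windows[:, 1]


def make_window_grid(
    model: TranscriptModel | int,
    window_length: int,
    step: int,
    transcript_id: str | None = None,
) -> WindowGrid:
    """Tile a transcript with sliding windows.

    Starts are ``0, step, 2*step, ...``; each window is
    ``[start, start + window_length)`` and the grid stops with the
    first window reaching the transcript end (truncated there, but
    kept at least ``step`` long — a shorter final tail is absorbed
    into the preceding window).  A ``window_length`` exceeding the
    transcript yields a single full-length window.
    """
    if isinstance(model, TranscriptModel):
        length = model.spliced_length
        tid = model.transcript_id
    else:
        length = int(model)
        tid = transcript_id if transcript_id is not None else ""
    if step < 1:
        raise ValueError("step must be >= 1")
    if window_length < step:
        raise ValueError("window_length must be >= step")
    if length < 1:
        raise ValueError("transcript length must be >= 1")
    if window_length >= length:
        windows = np.array([[0, length]], dtype=np.int64)
        return WindowGrid(tid, window_length, step, windows)
    n_full = max(1, int(np.ceil((length - window_length) / step)))
    starts = np.arange(n_full, dtype=np.int64) * step
    ends = starts + window_length
    tail_start = starts[-1] + step
    if length - tail_start >= step:
        starts = np.append(starts, tail_start)
        ends = np.append(ends, length)
    else:
        ends[-1] = length
    return WindowGrid(tid, window_length, step, np.column_stack([starts, ends]))


def window_table(
    models: Iterable[TranscriptModel],
    window_length: int,
    step: int,
) -> pd.DataFrame:
    """Concatenated window grid for many transcripts.

    Returns a DataFrame with columns ``transcript_id, window_start,
    window_end``, sorted by ``(transcript_id, window_start)`` — the
    skeleton onto which per-library count columns are attached.
    """
    frames = []
    for m in models:
        grid = make_window_grid(m, window_length, step)
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": m.transcript_id,
                    "window_start": grid.starts,
                    "window_end": grid.ends,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["transcript_id", "window_start", "window_end"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["transcript_id", "window_start"], kind="stable").reset_index(
        drop=True
    )


def normalize_windows(raw: Sequence[float], pseudocount: float = 1.0) -> np.ndarray:
    """Pseudocount-transform and median-normalize window counts.

    ``norm_w = (raw_w + pseudocount) / median(raw + pseudocount)``.  The
    median of an even number of windows is the mean of the two central
    order statistics.  An all-zero library normalizes to all ones (the
    pseudocount keeps the median positive).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("need at least one window")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    shifted = raw + pseudocount
    return shifted / np.median(shifted)


def normalize_table(
    windows: pd.DataFrame,
    lib_cols: Sequence[str],
    pseudocount: float = 1.0,
    per_transcript: bool = False,
) -> pd.DataFrame:
    """Median-normalize the count columns of a window table.

    By default the median is taken per library over all windows of all
    transcripts (a single global median per library); ``per_transcript``
    switches to a per-transcript median.
    """
    out = windows.copy()
    if per_transcript:
        for col in lib_cols:
            shifted = windows[col].to_numpy(dtype=float) + pseudocount
            med = (
                pd.Series(shifted)
                .groupby(windows["transcript_id"].to_numpy())
                .transform("median")
                .to_numpy()
            )
            out[col] = shifted / med
    else:
        for col in lib_cols:
            out[col] = normalize_windows(windows[col].to_numpy(), pseudocount)
    return out


def poi_scores(ip_norm: Sequence[float], input_norm: Sequence[float]) -> np.ndarray:
    """Peak-over-input score per window: ``ip_norm / input_norm``."""
    ip_norm = np.asarray(ip_norm, dtype=float)
    input_norm = np.asarray(input_norm, dtype=float)
    if ip_norm.shape != input_norm.shape:
        raise ValueError("IP and input scores computed on different grids")
    return ip_norm / input_norm


# ---------------------------------------------------------------------------
# Annotation import
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def _transcript_coordinate(exons, strand: str, genomic: int) -> int:
    """0-based transcript coordinate of a 1-based genomic position.

    ``exons`` are (start, end) 1-based inclusive pairs sorted in genomic
    order.
    """
    offset = 0
    if strand == "-":
        for start, end in sorted(exons, key=lambda e: -e[1]):
            if start <= genomic <= end:
                return offset + (end - genomic)
            offset += end - start + 1
    else:
        for start, end in sorted(exons):
            if start <= genomic <= end:
                return offset + (genomic - start)
            offset += end - start + 1
    raise ValueError(f"genomic position {genomic} not inside any exon")


def select_longest_isoform(annotation: str) -> list[TranscriptModel]:
    """Pick one transcript model per gene from a GFF3/GTF file.

    For each gene the isoform with the largest spliced exon length is
    chosen; ties are broken by the lexicographically smallest transcript
    id.  Transcripts lacking CDS features (or with a CDS length that is
    not a multiple of 3) are excluded with a warning.

    Parameters
    ----------
    annotation : str
        Path to a GFF3/GTF file with a gene -> transcript -> exon/CDS
        hierarchy.
    """
    import gffutils

    db = gffutils.create_db(
        annotation,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: list[TranscriptModel] = []
    for gene in db.features_of_type("gene"):
        best: tuple[int, str, TranscriptModel] | None = None
        for tx in db.children(gene, featuretype=_TRANSCRIPT_TYPES, level=1):
            exons = [(f.start, f.end) for f in db.children(tx, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
            if not exons:
                exons = sorted(cds)
            if not cds:
                logger.warning("transcript %s has no CDS; excluded", tx.id)
                continue
            spliced_length = sum(e - s + 1 for s, e in exons)
            cds_length = sum(e - s + 1 for s, e in cds)
            if tx.strand == "-":
                first_cds_base = max(e for _, e in cds)
            else:
                first_cds_base = min(s for s, _ in cds)
            try:
                cds_start = _transcript_coordinate(exons, tx.strand, first_cds_base)
                model = TranscriptModel(
                    transcript_id=tx.id,
                    spliced_length=spliced_length,
                    cds_start=cds_start,
                    cds_end=cds_start + cds_length,
                    gene_id=gene.id,
                )
            except ValueError as exc:
                logger.warning("transcript %s excluded: %s", tx.id, exc)
                continue
            # Larger spliced length wins; on a tie the smaller id wins.
            key = (spliced_length, tx.id)
            if best is None or key[0] > best[0] or (key[0] == best[0] and key[1] < best[1]):
                best = (spliced_length, tx.id, model)
        if best is not None:
            models.append(best[2])
    return models
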