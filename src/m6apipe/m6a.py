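"""m6A peak calling from IP/input sliding-window coverage.

The caller follows the windowed MeRIP-seq recipe: per IP replicate,
windows whose median-normalized coverage (peak-over-median score, POM)
exceeds a threshold are condensed into candidate regions; candidate
regions are unified across replicates by interval overlap; each unified
region's peak-over-input score (POI, mean IP norm / mean input norm over
the region's windows) is evaluated in every replicate; and a region is a
putative m6A site when its POI exceeds the threshold in at least
``min_replicates`` of the replicates (default 2 of 3).  All thresholds
are strict ``>`` comparisons.

A putative site is condition-specific when no grid window overlapping it
also overlaps a putative site of the other condition; otherwise it is
shared.
"""
from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .coverage import normalize_table

__all__ = [
    "PeakRegion",
    "condense_significant_windows",
    "region_poi",
    "consensus_call",
    "call_m6a_peaks",
    "classify_condition_specificity",
    "match_intervals",
]


@dataclasses.dataclass
class PeakRegion:
    """A condensed run of significant windows on one transcript."""

    transcript_id: str
    start: int
    end: int
    per_replicate_poi: list[float]
    n_supporting: int
    status: str  # "putative_site" | "rejected"
    condition_label: str = "unassigned"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty region")
        if self.n_supporting > len(self.per_replicate_poi):
            raise ValueError("n_supporting exceeds replicate count")


def condense_significant_windows(
    windows: np.ndarray, pom: Sequence[float], pom_threshold: float = 3.0
) -> list[tuple[int, int]]:
    """Merge runs of consecutive significant windows into regions.

    ``windows`` is an ``(n, 2)`` array ordered by start.  Windows with
    ``pom > pom_threshold`` that are consecutive on the grid (so their
    intervals overlap or abut) merge into one region spanning the
    minimum start to the maximum end; a non-significant window in
    between splits regions.
    """
    pom = np.asarray(pom, dtype=float)
    sig = np.flatnonzero(pom > pom_threshold)
    # merge runs of consecutive grid indices
    merged_idx: list[list[int]] = []
    for idx in sig:
        if merged_idx and idx == merged_idx[-1][1] + 1:
            merged_idx[-1][1] = idx
        else:
            merged_idx.append([idx, idx])
    return [
        (int(windows[a, 0]), int(windows[b, 1])) for a, b in merged_idx
    ]


def region_poi(
    region: tuple[int, int],
    windows: np.ndarray,
    ip_norm: Sequence[float],
    input_norm: Sequence[float],
) -> float:
    """POI of a region: mean IP norm over intersecting windows / mean input norm."""
    start, end = region
    ip_norm = np.asarray(ip_norm, dtype=float)
    input_norm = np.asarray(input_norm, dtype=float)
    hit = (windows[:, 0] < end) & (windows[:, 1] > start)
    if not hit.any():
        raise ValueError(f"region [{start}, {end}) intersects no window")
    return float(ip_norm[hit].mean() / input_norm[hit].mean())


def _union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of overlapping (not merely abutting) intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def consensus_call(
    transcript_id: str,
    windows: np.ndarray,
    ip_norms: Sequence[Sequence[float]],
    input_norms: Sequence[Sequence[float]],
    pom_threshold: float = 3.0,
    poi_threshold: float = 3.0,
    min_replicates: int = 2,
    pom_scores: Sequence[Sequence[float]] | None = None,
) -> list[PeakRegion]:
    """Replicate-consensus peak call for one transcript.

    Candidate regions are condensed per replicate from POM-significant
    windows, unified across replicates by interval overlap, and each
    unified region's POI is evaluated in every replicate; a region with
    POI above threshold in at least ``min_replicates`` replicates is a
    putative site.  ``pom_scores`` (default: the IP norm scores
    themselves) lets the caller gate candidates on a different
    normalization than the one POI is computed from.
    """
    n_reps = len(ip_norms)
    if n_reps != len(input_norms):
        raise ValueError("IP and input replicate counts differ")
    if n_reps < min_replicates:
        raise ValueError(
            f"{n_reps} replicates cannot satisfy a {min_replicates}-replicate consensus"
        )
    candidates: list[tuple[int, int]] = []
    for pom in pom_scores if pom_scores is not None else ip_norms:
        candidates.extend(condense_significant_windows(windows, pom, pom_threshold))
    peaks = []
    for region in _union_intervals(candidates):
        pois = [
            region_poi(region, windows, ip, inp)
            for ip, inp in zip(ip_norms, input_norms)
        ]
        n_support = int(sum(p > poi_threshold for p in pois))
        peaks.append(
            PeakRegion(
                transcript_id=transcript_id,
                start=region[0],
                end=region[1],
                per_replicate_poi=pois,
                n_supporting=n_support,
                status="putative_site" if n_support >= min_replicates else "rejected",
            )
        )
    return peaks


def call_m6a_peaks(
    windows: pd.DataFrame,
    ip_libs: Sequence[str],
    input_libs: Sequence[str],
    pom_threshold: float = 3.0,
    poi_threshold: float = 3.0,
    min_replicates: int = 2,
    pseudocount: float = 1.0,
    pom_mode: str = "union",
    keep_rejected: bool = False,
) -> pd.DataFrame:
    """Call putative m6A sites on a window-count table.

    ``windows`` carries columns ``transcript_id, window_start,
    window_end`` plus one raw-count column per library.  IP and input
    libraries are paired by position in ``ip_libs``/``input_libs``.
    Returns a table of regions with per-replicate POI columns
    (``poi_rep1 ...``), support count and status.

    ``pom_mode`` selects the median used for the POM gate: ``"global"``
    (library median over all windows), ``"per_transcript"`` (the
    transcript's own median), or ``"union"`` (default; a window is a
    candidate when it exceeds the threshold under either median).  The
    global median reads enrichment on an absolute scale but saturates
    on transcripts whose whole coverage sits far from the library
    median; the per-transcript median reads enrichment relative to the
    transcript's own background but degrades when a peak spans most of
    a short transcript.  POI scores always use the library-median
    normalization (the scale cancels in the ratio).
    """
    if pom_mode not in ("global", "per_transcript", "union"):
        raise ValueError("pom_mode must be 'global', 'per_transcript' or 'union'")
    libs = list(ip_libs) + list(input_libs)
    norm = normalize_table(windows, libs, pseudocount)
    norm_tx = (
        normalize_table(windows, list(ip_libs), pseudocount, per_transcript=True)
        if pom_mode in ("per_transcript", "union")
        else None
    )
    rows = []
    for tid, sub in norm.groupby("transcript_id", sort=True):
        grid = sub[["window_start", "window_end"]].to_numpy()
        ip_norms = [sub[c].to_numpy() for c in ip_libs]
        input_norms = [sub[c].to_numpy() for c in input_libs]
        if pom_mode == "global":
            pom_scores = ip_norms
        else:
            sub_tx = norm_tx.loc[sub.index]
            tx_scores = [sub_tx[c].to_numpy() for c in ip_libs]
            if pom_mode == "per_transcript":
                pom_scores = tx_scores
            else:
                # a window passes the gate when either score clears it
                pom_scores = [np.maximum(g, t) for g, t in zip(ip_norms, tx_scores)]
        for peak in consensus_call(
            tid, grid, ip_norms, input_norms, pom_threshold, poi_threshold,
            min_replicates, pom_scores=pom_scores,
        ):
            if peak.status != "putative_site" and not keep_rejected:
                continue
            row = {
                "transcript_id": peak.transcript_id,
                "start": peak.start,
                "end": peak.end,
                "n_supporting": peak.n_supporting,
                "status": peak.status,
                "condition_label": peak.condition_label,
            }
            for i, p in enumerate(peak.per_replicate_poi, start=1):
                row[f"poi_rep{i}"] = p
            rows.append(row)
    columns = ["transcript_id", "start", "end", "n_supporting", "status", "condition_label"]
    columns += [f"poi_rep{i}" for i in range(1, len(ip_libs) + 1)]
    return pd.DataFrame(rows, columns=columns)


def classify_condition_specificity(
    peaks_a: pd.DataFrame,
    peaks_b: pd.DataFrame,
    windows: pd.DataFrame,
    label_a: str = "condition_A_specific",
    label_b: str = "condition_B_specific",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label putative sites as condition-specific or shared.

    A site of condition A is A-specific iff no grid window overlapping
    it also overlaps a putative site of condition B (the significance
    map of B is the set of windows inside B's putative sites); sites
    failing that are shared.  The rule is applied symmetrically.
    """

    def _sig_windows(peaks: pd.DataFrame) -> dict[str, np.ndarray]:
        out: dict[str, list] = {}
        grid = {
            tid: sub[["window_start", "window_end"]].to_numpy()
            for tid, sub in windows.groupby("transcript_id", sort=False)
        }
        sig = {}
        for tid, g in grid.items():
            mask = np.zeros(len(g), dtype=bool)
            sub = peaks[(peaks["transcript_id"] == tid) & (peaks["status"] == "putative_site")]
            for s, e in zip(sub["start"], sub["end"]):
                mask |= (g[:, 0] < e) & (g[:, 1] > s)
            sig[tid] = (g, mask)
        return sig

    def _label(peaks: pd.DataFrame, other_sig, specific_label: str) -> pd.DataFrame:
        out = peaks.copy()
        labels = []
        for row in peaks.itertuples(index=False):
            if row.status != "putative_site":
                labels.append("unassigned")
                continue
            g, mask = other_sig.get(row.transcript_id, (None, None))
            if g is None:
                labels.append(specific_label)
                continue
            overlapping = (g[:, 0] < row.end) & (g[:, 1] > row.start)
            labels.append("shared" if (overlapping & mask).any() else specific_label)
        out["condition_label"] = labels
        return out

    sig_a = _sig_windows(peaks_a)
    sig_b = _sig_windows(peaks_b)
    return _label(peaks_a, sig_b, label_a), _label(peaks_b, sig_a, label_b)


def match_intervals(
    called: pd.DataFrame, truth_intervals: dict[str, list[tuple[int, int]]]
) -> tuple[float, float]:
    """Recall and precision of called regions against truth intervals.

    A call matches the truth when the intervals overlap by >= 1 nt.
    Returns ``(recall, precision)``; an empty truth gives recall 1.0 and
    an empty call set gives precision 1.0 (nothing wrongly called).
    """
    n_truth = sum(len(v) for v in truth_intervals.values())
    calls = called[called["status"] == "putative_site"] if "status" in called else called
    n_calls = len(calls)
    hit_truth = 0
    for tid, intervals in truth_intervals.items():
        sub = calls[calls["transcript_id"] == tid]
        for s, e in intervals:
            if ((sub["start"] < e) & (sub["end"] > s)).any():
                hit_truth += 1
    hit_calls = 0
    for row in calls.itertuples(index=False):
        for s, e in truth_intervals.get(row.transcript_id, []):
            if row.start < e and row.end > s:
                hit_calls += 1
                break
    recall = hit_truth / n_truth if n_truth else 1.0
    precision = hit_calls / n_calls if n_calls else 1.0
    return recall, precision
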