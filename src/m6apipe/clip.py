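"""FA-CLIP binding-site calling with a control floor and empirical FDR.

The caller scores IP/input window ratios (POI) on a fine sliding grid
(step 10 nt), then applies three gates:

1. a sensitivity floor — the 90th percentile of POI scores pooled
   across non-specific (YFP-like) control libraries; windows below the
   floor are removed;
2. a per-transcript Z-score on the window POI distribution (by default
   on the log scale around a median/MAD background estimate), strict
   ``z > 2.576``;
3. an empirical false discovery rate, obtained by re-running the whole
   calling procedure with IP and input inverted (input/IP ratios,
   floor recomputed on inverted control ratios):
   ``FDR = inverted call count / forward call count``, attached
   globally to the run; calls are kept only when ``FDR < 0.05``.

Windows surviving the floor and Z gates are condensed into sites as in
the m6A caller (with a minimum run of consecutive significant
windows), sites must pass independently in every replicate, and the
reported site is the interval intersection across replicates.
"""
from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .coverage import normalize_table
from .m6a import condense_significant_windows

__all__ = [
    "sensitivity_floor",
    "transcript_zscores",
    "empirical_fdr",
    "call_clip_sites",
    "ClipRunStats",
]


def sensitivity_floor(control_pois: Sequence[float], percentile: float = 90.0) -> float:
    """Floor = the given percentile of pooled control-window POI scores.

    Linear interpolation between order statistics (numpy's default
    convention), e.g. the 90th percentile of {1..10} is 9.1.
    """
    control_pois = np.asarray(control_pois, dtype=float)
    if control_pois.size == 0:
        raise ValueError("no control windows to set the sensitivity floor")
    return float(np.percentile(control_pois, percentile))


def transcript_zscores(pois: Sequence[float]) -> np.ndarray:
    """Standard scores of window POI within one transcript.

    Sample standard deviation (n-1); a zero-variance transcript yields
    z = 0 everywhere so nothing passes a positive threshold.
    """
    pois = np.asarray(pois, dtype=float)
    if pois.size < 3:
        raise ValueError("need >= 3 windows with defined POI")
    sd = pois.std(ddof=1)
    if sd == 0:
        return np.zeros_like(pois)
    return (pois - pois.mean()) / sd


def empirical_fdr(n_forward: int, n_inverted: int) -> float:
    """Global empirical FDR = inverted pass count / forward pass count.

    A forward count of zero gives 0 when nothing passes inverted either,
    else 1.  The raw ratio may exceed 1; clamp on output if reporting.
    """
    if n_forward == 0:
        return 0.0 if n_inverted == 0 else 1.0
    return n_inverted / n_forward


@dataclasses.dataclass
class ClipRunStats:
    """Diagnostics of one CLIP calling run.

    Window counts are summed over replicates; site counts are after
    replicate intersection.
    """

    floors: list[float]
    floors_inverted: list[float]
    n_forward_windows: int
    n_inverted_windows: int
    n_forward_sites: int
    n_inverted_sites: int
    fdr: float


def _zscores_by_transcript(
    tids: np.ndarray, values: np.ndarray, robust: bool = False
) -> np.ndarray:
    """Per-transcript standard scores; transcripts with < 3 windows get 0.

    ``robust`` replaces mean/sd with median and the consistent MAD
    estimate of the standard deviation (1.4826 * MAD), which keeps the
    background location/scale estimate uncontaminated by the bound
    windows themselves.
    """
    z = np.zeros_like(values, dtype=float)
    for _tid, sub in pd.Series(values).groupby(tids):
        idx = sub.index.to_numpy()
        if len(idx) < 3:
            continue  # transcript skipped: too few windows for a Z-score
        vals = sub.to_numpy()
        if robust:
            center = np.median(vals)
            scale = 1.4826 * np.median(np.abs(vals - center))
        else:
            center = vals.mean()
            scale = vals.std(ddof=1)
        z[idx] = 0.0 if scale == 0 else (vals - center) / scale
    return z


def _pass_mask(
    tids: np.ndarray,
    poi: np.ndarray,
    control_ratios: np.ndarray,
    z_threshold: float,
    percentile: float,
    use_floor: bool = True,
    use_log: bool = True,
    robust: bool = True,
) -> tuple[np.ndarray, float]:
    floor = sensitivity_floor(control_ratios, percentile)
    scores = np.log(poi) if use_log else poi
    z = _zscores_by_transcript(tids, scores, robust=robust)
    mask = z > z_threshold
    if use_floor:
        mask &= poi >= floor
    return mask, floor


def _replicate_sites(
    norm: pd.DataFrame,
    tids: np.ndarray,
    grid_by_tid: dict,
    ip_libs: Sequence[str],
    input_libs: Sequence[str],
    control_libs: Sequence[str],
    z_threshold: float,
    percentile: float,
    use_floor: bool,
    use_log: bool,
    robust: bool,
    min_windows: int,
    inverted: bool,
) -> tuple[list[dict[str, list[tuple[int, int]]]], list[float], int]:
    """Floor+Z gated, condensed candidate sites per replicate.

    Regions supported by fewer than ``min_windows`` consecutive passing
    windows are dropped: with a 10-nt step any real footprint spans
    several overlapping windows, so an isolated significant window is
    treated as noise.
    """
    per_rep: list[dict[str, list[tuple[int, int]]]] = []
    floors: list[float] = []
    n_windows = 0
    for ip, inp in zip(ip_libs, input_libs):
        poi = norm[ip].to_numpy() / norm[inp].to_numpy()
        ctrl = np.concatenate(
            [
                norm[c].to_numpy() / norm[input_libs[i % len(input_libs)]].to_numpy()
                for i, c in enumerate(control_libs)
            ]
        )
        if inverted:
            poi, ctrl = 1.0 / poi, 1.0 / ctrl
        mask, floor = _pass_mask(
            tids, poi, ctrl, z_threshold, percentile, use_floor, use_log, robust
        )
        floors.append(floor)
        n_windows += int(mask.sum())
        rep_sites: dict[str, list[tuple[int, int]]] = {}
        if mask.any():
            flags = pd.Series(mask)
            for tid, sub in flags.groupby(tids):
                if not sub.any():
                    continue
                m = sub.to_numpy()
                grid = grid_by_tid[tid]
                regions = []
                for s, e in condense_significant_windows(grid, m.astype(float), 0.5):
                    n_sig = int(m[(grid[:, 0] >= s) & (grid[:, 1] <= e)].sum())
                    if n_sig >= min_windows:
                        regions.append((s, e))
                if regions:
                    rep_sites[tid] = regions
        per_rep.append(rep_sites)
    return per_rep, floors, n_windows


def _intersect_replicates(
    per_rep: list[dict[str, list[tuple[int, int]]]]
) -> list[tuple[str, int, int]]:
    """Sites passing independently in every replicate (interval intersection)."""
    out = []
    base = per_rep[0] if per_rep else {}
    for tid, intervals in base.items():
        for s, e in intervals:
            cur = (s, e)
            ok = True
            for other in per_rep[1:]:
                hits = [
                    (max(cur[0], os), min(cur[1], oe))
                    for os, oe in other.get(tid, [])
                    if os < cur[1] and oe > cur[0]
                ]
                if not hits:
                    ok = False
                    break
                cur = max(hits, key=lambda iv: iv[1] - iv[0])
            if ok:
                out.append((tid, cur[0], cur[1]))
    return out


def call_clip_sites(
    windows: pd.DataFrame,
    ip_libs: Sequence[str],
    input_libs: Sequence[str],
    control_libs: Sequence[str],
    z_threshold: float = 2.576,
    fdr_threshold: float = 0.05,
    percentile: float = 90.0,
    pseudocount: float = 1.0,
    use_floor: bool = True,
    use_log: bool = True,
    robust: bool = True,
    min_windows: int = 2,
    fdr_level: str = "site",
) -> tuple[pd.DataFrame, ClipRunStats]:
    """Call binding sites on a window-count table.

    IP and input libraries are paired per replicate by position;
    control libraries are each ratioed against the positionally
    matching input library (cycling when counts differ) and pooled to
    set the floor.  Candidate sites must pass the floor+Z gates
    independently in every replicate and are intersected.  The
    empirical FDR re-runs the identical procedure with IP and input
    inverted; with ``fdr_level="site"`` (default) the ratio compares
    inverted to forward site counts after replicate intersection, with
    ``fdr_level="window"`` it compares summed per-replicate passing
    window counts.  All forward sites are kept iff FDR < threshold.

    By default Z-scores are taken on log(POI) (ratio noise is
    multiplicative) around a median/MAD background estimate
    (``robust``), so the bound windows themselves do not contaminate
    the background location and scale; ``use_log=False, robust=False``
    reproduces the plain mean/sd Z on linear POI.
    """
    if not control_libs:
        raise ValueError("control libraries are required to set the sensitivity floor")
    if len(ip_libs) != len(input_libs):
        raise ValueError("IP and input replicate counts differ")
    if fdr_level not in ("site", "window", "per_transcript"):
        raise ValueError("fdr_level must be 'site', 'window' or 'per_transcript'")
    libs = list(ip_libs) + list(input_libs) + list(control_libs)
    norm = normalize_table(windows, libs, pseudocount)
    tids = norm["transcript_id"].to_numpy()
    grid_by_tid = {
        tid: sub[["window_start", "window_end"]].to_numpy()
        for tid, sub in norm.groupby("transcript_id", sort=False)
    }
    args = (norm, tids, grid_by_tid, ip_libs, input_libs, control_libs,
            z_threshold, percentile, use_floor, use_log, robust, min_windows)
    fwd_rep, floors, n_fwd_windows = _replicate_sites(*args, inverted=False)
    inv_rep, floors_inv, n_inv_windows = _replicate_sites(*args, inverted=True)
    fwd_sites = _intersect_replicates(fwd_rep)
    inv_sites = _intersect_replicates(inv_rep)
    if fdr_level == "window":
        fdr = empirical_fdr(n_fwd_windows, n_inv_windows)
    else:
        fdr = empirical_fdr(len(fwd_sites), len(inv_sites))
    stats = ClipRunStats(
        floors=floors,
        floors_inverted=floors_inv,
        n_forward_windows=n_fwd_windows,
        n_inverted_windows=n_inv_windows,
        n_forward_sites=len(fwd_sites),
        n_inverted_sites=len(inv_sites),
        fdr=fdr,
    )
    rows = []
    if fdr_level == "per_transcript":
        fwd_per = {}
        inv_per = {}
        for tid, *_ in fwd_sites:
            fwd_per[tid] = fwd_per.get(tid, 0) + 1
        for tid, *_ in inv_sites:
            inv_per[tid] = inv_per.get(tid, 0) + 1
        kept = [
            (tid, s, e, empirical_fdr(fwd_per[tid], inv_per.get(tid, 0)))
            for tid, s, e in fwd_sites
            if empirical_fdr(fwd_per[tid], inv_per.get(tid, 0)) < fdr_threshold
        ]
    elif fdr < fdr_threshold:
        kept = [(tid, s, e, fdr) for tid, s, e in fwd_sites]
    else:
        kept = []
    for tid, s, e, f in kept:
        rows.append(
            {
                "transcript_id": tid,
                "start": s,
                "end": e,
                "status": "putative_site",
                "n_replicates": len(ip_libs),
                "fdr": min(f, 1.0),
            }
        )
    sites = pd.DataFrame(
        rows, columns=["transcript_id", "start", "end", "status", "n_replicates", "fdr"]
    )
    return sites, stats
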