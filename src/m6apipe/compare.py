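"""Subgroup comparisons: rank tests, labels and the stability/TE scatter.

The statistical layer mirrors how the upstream analyses are compared:
cumulative distributions of per-transcript half-life or TE changes in
transcript subgroups ("m6A & ECT2 targets" vs transcripts with neither
mark; elf18-inducible vs noninducible), tested with a two-sided
Mann-Whitney rank test, and the integration scatter of stability change
against TE change for inducible transcripts.

The Mann-Whitney implementation enumerates the exact null distribution
of U over rank assignments (midranks under ties) for small samples and
uses the tie-corrected normal approximation otherwise; the exact
two-sided p doubles the smaller tail, capped at 1.
"""
from __future__ import annotations

import dataclasses
from itertools import combinations
from math import comb
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SubgroupComparison",
    "mann_whitney",
    "define_subgroups",
    "stability_te_scatter",
]

#: Use exact enumeration when both groups are at most this large and the
#: number of combinations stays tractable.
EXACT_MAX_N = 20
EXACT_MAX_COMB = 200_000


@dataclasses.dataclass(frozen=True)
class SubgroupComparison:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p: float
    shift: float  # difference of medians, a - b


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2)


def mann_whitney(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> SubgroupComparison:
    """Two-sided Mann-Whitney test of two samples.

    The reported U is the statistic of group A.  Small samples are
    tested by exhaustive enumeration of rank assignments (ties handled
    through midranks); larger samples use the normal approximation with
    tie-corrected variance and no continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u = _u_statistic(ranks[:n_a], n_a)

    if max(n_a, n_b) <= EXACT_MAX_N and comb(n_a + n_b, n_a) <= EXACT_MAX_COMB:
        idx = range(n_a + n_b)
        base = n_a * (n_a + 1) / 2
        us = np.fromiter(
            (ranks[list(c)].sum() - base for c in combinations(idx, n_a)),
            dtype=float,
            count=comb(n_a + n_b, n_a),
        )
        lo = float((us <= u + 1e-12).mean())
        hi = float((us >= u - 1e-12).mean())
        p = min(1.0, 2 * min(lo, hi))
    else:
        mu = n_a * n_b / 2
        n = n_a + n_b
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        var = n_a * n_b / 12 * (n + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (u - mu) / np.sqrt(var)
            p = float(2 * sps.norm.sf(abs(z)))
    return SubgroupComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        n_a=n_a,
        n_b=n_b,
        u_statistic=u,
        p=max(min(p, 1.0), np.nextafter(0, 1)),
        shift=float(np.median(a) - np.median(b)),
    )


def define_subgroups(
    transcript_ids: Sequence[str],
    m6a_transcripts: Sequence[str],
    clip_transcripts: Sequence[str],
    inducible: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-transcript subgroup labels.

    ``target`` = at least one putative m6A site AND at least one CLIP
    binding site; ``control`` = neither; anything else is
    ``unlabeled``.  When an inducibility table (transcript_id,
    inducible) is given, an independent ``inducible`` column is merged.
    """
    m6a = set(m6a_transcripts)
    clip = set(clip_transcripts)
    labels = []
    for tid in transcript_ids:
        has_m6a, has_clip = tid in m6a, tid in clip
        if has_m6a and has_clip:
            labels.append("target")
        elif not has_m6a and not has_clip:
            labels.append("control")
        else:
            labels.append("unlabeled")
    out = pd.DataFrame({"transcript_id": list(transcript_ids), "group": labels})
    if inducible is not None:
        out = out.merge(
            inducible[["transcript_id", "inducible"]], on="transcript_id", how="left"
        )
        out["inducible"] = out["inducible"].astype("boolean").fillna(False).astype(bool)
    return out


def stability_te_scatter(
    halflife_changes: pd.DataFrame,
    te_changes: pd.DataFrame,
    labels: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Paired (half-life change, TE change) table for inducible transcripts.

    One row per elf18-inducible transcript present in both analyses;
    transcripts missing either metric are excluded and counted.
    Quadrant counts use the sign of (log2 half-life change, log2 TE
    change).
    """
    merged = halflife_changes.merge(te_changes, on="transcript_id", how="outer")
    merged = merged.merge(labels, on="transcript_id", how="left")
    inducible = merged[merged["inducible"].astype("boolean").fillna(False).astype(bool)]
    complete = inducible.dropna(subset=["log2_halflife_change", "log2_te_change"])
    excluded = len(inducible) - len(complete)
    dh = complete["log2_halflife_change"].to_numpy()
    dt = complete["log2_te_change"].to_numpy()
    quadrants = {
        "stabilized_down": int(((dh > 0) & (dt < 0)).sum()),
        "stabilized_up": int(((dh > 0) & (dt >= 0)).sum()),
        "destabilized_down": int(((dh <= 0) & (dt < 0)).sum()),
        "destabilized_up": int(((dh <= 0) & (dt >= 0)).sum()),
        "excluded": excluded,
    }
    return complete.reset_index(drop=True), quadrants
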