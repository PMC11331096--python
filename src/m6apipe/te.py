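"""Polysome-based translation efficiency and elf18 inducibility.

TE of a transcript in one replicate is the ratio of size-factor
normalized polysome counts to normalized input counts (with a unit
pseudocount on the normalized scale by default); the reported TE is the
arithmetic mean over replicates.  Transcripts are classified as
elf18-inducible when their input abundance rises more than 1.5-fold
with a Benjamini-Hochberg adjusted p-value below 0.05; the test is a
Welch t-test on log2(normalized count + 1), swappable for an imported
external differential-expression table.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decay import size_factors

__all__ = ["compute_te", "call_inducible", "te_change"]


def compute_te(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    condition: str,
    pseudocount: float = 1.0,
    factors: pd.Series | None = None,
    mean: str = "arithmetic",
) -> pd.DataFrame:
    """Per-transcript TE for one condition.

    ``metadata`` must carry (library, condition, fraction, replicate)
    rows describing the columns of ``counts``; input and polysome
    libraries are paired by replicate number.  Returns a table with one
    ``te_rep<r>`` column per replicate and ``te_mean``.  Replicates
    missing either fraction are skipped; with ``pseudocount == 0``,
    transcripts with a zero input in every replicate are excluded.
    """
    meta = metadata[metadata["condition"] == condition]
    if factors is None:
        factors = size_factors(counts[metadata["library"]])
    reps = sorted(meta["replicate"].unique())
    te_cols = {}
    for r in reps:
        sub = meta[meta["replicate"] == r]
        inp = sub[sub["fraction"] == "input"]["library"]
        pol = sub[sub["fraction"] == "polysome"]["library"]
        if len(inp) != 1 or len(pol) != 1:
            continue  # unpaired replicate skipped
        inp_n = counts[inp.iloc[0]].to_numpy(float) / factors[inp.iloc[0]] + pseudocount
        pol_n = counts[pol.iloc[0]].to_numpy(float) / factors[pol.iloc[0]] + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            te_cols[f"te_rep{r}"] = np.where(inp_n > 0, pol_n / inp_n, np.nan)
    if not te_cols:
        raise ValueError(f"no paired input/polysome replicates for {condition!r}")
    out = pd.DataFrame(te_cols, index=counts.index)
    vals = out.to_numpy()
    if mean == "arithmetic":
        out["te_mean"] = np.nanmean(vals, axis=1)
    elif mean == "geometric":
        out["te_mean"] = np.exp(np.nanmean(np.log(vals), axis=1))
    else:
        raise ValueError(f"unknown mean {mean!r}")
    out.insert(0, "transcript_id", counts.index)
    out.insert(1, "condition", condition)
    return out[np.isfinite(out["te_mean"])].reset_index(drop=True)


def call_inducible(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    factors: pd.Series | None = None,
    external: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Classify transcripts as elf18-inducible from input libraries.

    Fold-change is the ratio of mean normalized input counts
    (elf18/mock, +1 pseudocount); p-values come from a Welch t-test on
    log2(normalized count + 1) with Benjamini-Hochberg adjustment
    across transcripts, unless an ``external`` differential-expression
    table (transcript_id, log2FC, padj) is supplied, in which case it
    is used verbatim.  Inducible iff ``fc > fc_threshold`` and
    ``p_adj < alpha`` (strict).
    """
    inputs = metadata[metadata["fraction"] == "input"]
    mock_libs = inputs[inputs["condition"] == "mock"]["library"].tolist()
    elf_libs = inputs[inputs["condition"] == "elf18"]["library"].tolist()
    if min(len(mock_libs), len(elf_libs)) < 2:
        raise ValueError("need >= 2 input replicates per condition")
    if factors is None:
        factors = size_factors(counts[metadata["library"]])
    mock = counts[mock_libs].to_numpy(float) / factors[mock_libs].to_numpy()
    elf = counts[elf_libs].to_numpy(float) / factors[elf_libs].to_numpy()
    fc = (elf.mean(axis=1) + 1) / (mock.mean(axis=1) + 1)
    if external is not None:
        ext = external.set_index("transcript_id").reindex(counts.index)
        fc = np.exp2(ext["log2FC"].to_numpy(float))
        padj = ext["padj"].to_numpy(float)
    else:
        t, p = stats.ttest_ind(
            np.log2(elf + 1), np.log2(mock + 1), axis=1, equal_var=False
        )
        p = np.where(np.isnan(p), 1.0, p)
        padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "transcript_id": counts.index,
            "input_fc": fc,
            "p_adj": padj,
            "inducible": (fc > fc_threshold) & (padj < alpha),
        }
    ).reset_index(drop=True)


def te_change(
    te_mutant: pd.DataFrame,
    te_wildtype: pd.DataFrame,
    labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-transcript log2 TE ratio mutant/wild type.

    Transcripts must have a finite positive ``te_mean`` in both inputs;
    optional ``labels`` (transcript_id plus any label columns) are
    merged onto the output.
    """
    a = te_mutant.set_index("transcript_id")["te_mean"]
    b = te_wildtype.set_index("transcript_id")["te_mean"]
    common = a.index.intersection(b.index)
    a, b = a[common], b[common]
    ok = (a > 0) & (b > 0) & np.isfinite(a) & np.isfinite(b)
    out = pd.DataFrame(
        {
            "transcript_id": common[ok],
            "log2_te_change": np.log2(a[ok].to_numpy() / b[ok].to_numpy()),
        }
    )
    if labels is not None:
        out = out.merge(labels, on="transcript_id", how="left")
    return out.reset_index(drop=True)
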