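"""Regulatory potential (RP): distance-weighted sums of ChIP-seq peaks.

To apply network neighbor scoring to binding or histone-mark data, each
gene first gets a scalar regulatory-potential score summarizing the
peaks around its transcription start site:

    RP(g) = sum over peaks within ±window of the TSS of 2^(−d / d0)

where d is the distance in bases from the peak midpoint to the TSS, d0 is
the half-decay distance (default 10 kb: a peak 10 kb away counts half as
much as one at the TSS) and the window defaults to ±100 kb. The kernel is
an explicit, monotone exponential half-decay; the exact constants used by
upstream RP tools vary, so both are configurable. Strand never enters:
the window is symmetric around the TSS.

Peaks arrive as BED3+ intervals (0-based, half-open); the gene anchor is
a one-TSS-per-gene annotation table.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

BED_COLUMNS = ["chrom", "start", "end"]
TSS_COLUMNS = ["gene", "chrom", "tss", "strand"]


def read_peaks_bed(path) -> pd.DataFrame:
    """Read BED3+ peak intervals; extra columns beyond the first three are ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ParseError(f"{path}: BED needs >=3 columns, found {df.shape[1]}")
    peaks = df.iloc[:, :3].copy()
    peaks.columns = BED_COLUMNS
    validate_peaks(peaks)
    return peaks


def validate_peaks(peaks: pd.DataFrame) -> None:
    if not set(BED_COLUMNS) <= set(peaks.columns):
        raise ValidationError(f"peak table needs columns {BED_COLUMNS}")
    if (peaks["start"] >= peaks["end"]).any():
        bad = peaks[peaks["start"] >= peaks["end"]].index[:3].tolist()
        raise ValidationError(f"peaks with start >= end at rows {bad}")
    if peaks["chrom"].astype(str).str.len().eq(0).any():
        raise ValidationError("empty chromosome name in peak table")


def read_tss_annotation(path) -> pd.DataFrame:
    """Read a ``gene<TAB>chrom<TAB>tss<TAB>strand`` table (one TSS per gene)."""
    df = pd.read_csv(path, sep="\t", header=None, names=TSS_COLUMNS, comment="#")
    validate_annotation(df)
    return df


def validate_annotation(genes: pd.DataFrame) -> None:
    if len(genes) == 0:
        raise ValidationError("empty gene annotation")
    if not set(TSS_COLUMNS) <= set(genes.columns):
        raise ValidationError(f"annotation needs columns {TSS_COLUMNS}")
    if genes["gene"].duplicated().any():
        dups = genes.loc[genes["gene"].duplicated(), "gene"].tolist()[:5]
        raise ValidationError(f"annotation lists multiple TSS for gene(s) {dups}")
    if not genes["strand"].isin(["+", "-"]).all():
        raise ValidationError("strand must be '+' or '-'")


def regulatory_potential(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    decay_kb: float = 10.0,
    window_kb: float = 100.0,
) -> pd.Series:
    """Per-gene RP score: 2^(−d/decay) summed over peaks within the window.

    ``peaks`` and ``genes`` must share an assembly (caller's
    responsibility). An empty peak table yields all-zero RP, which is a
    valid (silent) profile. RP is additive over disjoint peak subsets and
    non-increasing as a peak moves away from the TSS.
    """
    if decay_kb <= 0 or window_kb <= 0:
        raise ValidationError("decay_kb and window_kb must be positive")
    validate_annotation(genes)
    if len(peaks) > 0:
        validate_peaks(peaks)
    decay_bp = decay_kb * 1000.0
    window_bp = window_kb * 1000.0

    centers_by_chrom: dict[str, np.ndarray] = {}
    if len(peaks) > 0:
        mid = (peaks["start"].to_numpy(dtype=float) + peaks["end"].to_numpy(dtype=float)) / 2.0
        for chrom, idx in peaks.groupby("chrom").indices.items():
            centers_by_chrom[str(chrom)] = np.sort(mid[idx])

    rp = np.zeros(len(genes))
    for i, (chrom, tss) in enumerate(zip(genes["chrom"].astype(str), genes["tss"])):
        centers = centers_by_chrom.get(chrom)
        if centers is None:
            continue
        lo = np.searchsorted(centers, tss - window_bp, side="left")
        hi = np.searchsorted(centers, tss + window_bp, side="right")
        if hi > lo:
            d = np.abs(centers[lo:hi] - tss)
            rp[i] = np.exp2(-d / decay_bp).sum()
    return pd.Series(rp, index=genes["gene"].to_numpy(), name="rp")


def center_rp(rp_matrix: pd.DataFrame) -> pd.DataFrame:
    """Center per-gene RP scores across profiled samples (mean subtraction).

    Delegates to the shared value-centering step so RP matrices and
    expression matrices are treated identically downstream.
    """
    from .scoring import center_values

    return center_values(rp_matrix)
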