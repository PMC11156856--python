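"""ATAC-seq insertion-level signal: pseudo reads, pileups and MAP quantification.

Each Tn5 insertion event is extended +/- 75 bp into a 150 bp pseudo read; the
pseudo-read pileup, scaled by sequencing depth, is the browser-style signal
profile. For cross-sample comparisons the pseudo reads overlapping each MAP
(major ATAC-seq peak) are counted into a MAP-by-sample matrix, which is then
normalized so every sample's total MAP signal equals that of the reference
sample — the one whose raw total is the median across samples.

Intervals are 0-based half-open throughout; overlap means >= 1 shared bp.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: Tn5 duplication offset: + strand cut sites shift +4, - strand -5.
TN5_SHIFT_PLUS = 4
TN5_SHIFT_MINUS = -5


def tn5_correct(positions: np.ndarray, strands: np.ndarray) -> np.ndarray:
    """Shift raw fragment ends to the Tn5 insertion centre (+4 / -5)."""
    positions = np.asarray(positions, dtype=np.int64)
    strands = np.asarray(strands)
    shift = np.where(strands == "+", TN5_SHIFT_PLUS, TN5_SHIFT_MINUS)
    return positions + shift


def pseudo_reads(
    events: np.ndarray, half_width: int = 75, chrom_length: int | None = None
) -> np.ndarray:
    """Extend insertion events into pseudo-read intervals.

    Each event at position p becomes [p - half_width, p + half_width), a
    2*half_width bp interval, clipped at chromosome bounds with a warning.
    Returns an (n, 2) array of half-open intervals.
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    events = np.asarray(events, dtype=np.int64)
    out = np.stack([events - half_width, events + half_width], axis=-1)
    lo = out[:, 0] < 0
    hi = chrom_length is not None and np.any(out[:, 1] > chrom_length)
    if lo.any() or hi:
        warnings.warn("pseudo reads clipped at chromosome bounds")
        out[:, 0] = np.maximum(out[:, 0], 0)
        if chrom_length is not None:
            out[:, 1] = np.minimum(out[:, 1], chrom_length)
    return out


def pileup_and_depth_normalize(
    intervals: np.ndarray,
    region: tuple[int, int],
    total_events_in_library: int,
    scale: float = 1e7,
) -> np.ndarray:
    """Per-bp pseudo-read coverage over a region, depth-normalized.

    Coverage is multiplied by ``scale / total_events_in_library`` so that
    libraries of different depth are comparable.
    """
    if total_events_in_library <= 0:
        raise ValueError("total_events_in_library must be > 0")
    start, end = region
    if end <= start:
        raise ValueError("region end must exceed region start")
    length = end - start
    diff = np.zeros(length + 1)
    intervals = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    s = np.clip(intervals[:, 0] - start, 0, length)
    e = np.clip(intervals[:, 1] - start, 0, length)
    np.add.at(diff, s, 1.0)
    np.add.at(diff, e, -1.0)
    coverage = np.cumsum(diff[:-1])
    return coverage * (scale / total_events_in_library)


def _check_maps(maps: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "start", "end", "name"}
    missing = required - set(maps.columns)
    if missing:
        raise ValueError(f"MAP table missing columns {sorted(missing)}")
    if maps["name"].duplicated().any():
        raise ValueError("MAP names must be unique")
    for chrom, grp in maps.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["end"].values[:-1] > g["start"].values[1:]).any():
            raise ValueError(f"overlapping MAP intervals on {chrom}")
    return maps


def count_map_matrix(
    sample_reads: dict[str, pd.DataFrame], maps: pd.DataFrame
) -> pd.DataFrame:
    """Count pseudo reads overlapping each MAP, per sample.

    ``sample_reads`` maps sample id to a frame with columns (chrom, start,
    end); ``maps`` is a BED-like frame with (chrom, start, end, name) and
    non-overlapping intervals. An overlap is >= 1 bp on half-open intervals.
    """
    maps = _check_maps(maps)
    out = pd.DataFrame(
        0, index=pd.Index(maps["name"], name="map"), columns=list(sample_reads)
    )
    for sample, reads in sample_reads.items():
        for _, row in maps.iterrows():
            on_chrom = reads[reads["chrom"] == row["chrom"]]
            hits = (on_chrom["start"] < row["end"]) & (on_chrom["end"] > row["start"])
            out.loc[row["name"], sample] = int(hits.sum())
    return out


def normalize_map_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its MAP total equals the median sample's total.

    The reference is the sample whose raw total is the median of all sample
    totals (lower median for an even sample count); its column is unchanged.
    """
    totals = m.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total MAP signal: {list(zero.index)}")
    order = totals.sort_values(kind="stable")
    reference = order.index[(len(order) - 1) // 2]
    target = totals[reference]
    return m * (target / totals)
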