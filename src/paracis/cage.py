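"""CAGE-style TSS processing: filtering, normalization, clustering, cap filter.

Implements the promoter-calling path for 5'-end (CAGE) libraries of a
paralogous locus:

* a stringent per-record architecture filter (template length, soft clipping,
  mismatches) feasible because samples are inbred and aligned to their own
  reference, so any mismatch is a library or sequencing artifact;
* a positional UMI deduplication for low-input libraries;
* power-law normalization of per-bp TSS counts to a reference distribution
  (exponent alpha, total T), so samples of different depth share a scale;
* distance-based tag clustering (distclu) run twice — a loose pass where any
  sample's pass-threshold signal seeds clusters and a strict pass requiring
  all samples — keeping loose clusters confirmed by a strict one, with the
  loose boundaries;
* the cap-signature filter retaining only clusters where more than 70% of
  reads begin with a reference-unencoded G (evidence of a capped 5' end).

Thresholds follow the published parameterization: clustering threshold 2,
maxDist 50 bp, singletons kept only above signal 4, cap fraction strictly
above 0.70.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class PeakCallConfig:
    threshold: float = 2.0
    max_dist: int = 50
    keep_singletons_above: float = 4.0

    def __post_init__(self) -> None:
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")
        if self.threshold < 0 or self.keep_singletons_above < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class PowerLawConfig:
    alpha: float = 1.2
    total: float = 1e6
    fit_range: tuple[float, float] = (5.0, 1000.0)

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError("alpha must be > 1")
        if self.total <= 0:
            raise ValueError("total must be > 0")


@dataclass
class TagCluster:
    """A strand-specific cluster of nearby TSS positions."""

    chrom: str
    strand: str
    start: int  # 0-based half-open over member positions
    end: int
    positions: tuple[int, ...]
    sample_signal: dict[str, float] = field(default_factory=dict)
    n_reads: int = 0
    n_capped: int = 0

    @property
    def cap_fraction(self) -> float:
        return self.n_capped / self.n_reads if self.n_reads else float("nan")

    def overlaps(self, other: "TagCluster") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


# -------------------------------------------------------------------------
# Alignment-level filters
# -------------------------------------------------------------------------

ARCHITECTURE_RULES = ("template_length", "soft_clip", "mismatch")


def architecture_filter(
    records: pd.DataFrame,
    max_tlen: int = 10_000,
    max_soft_clip: int = 3,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove records failing any architecture rule; report counts per rule.

    Rules: |template length| > 10 kb (cross-gene chimeras); soft clipping
    > 3 bp; any mismatch. A record may be counted under several rules.
    Requires columns ``tlen``, ``soft_clip`` and ``mismatches``.
    """
    for col in ("tlen", "soft_clip", "mismatches"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    if records["mismatches"].isna().any():
        raise ValueError("mismatch counts unavailable; cannot apply mismatch rule")
    bad_tlen = records["tlen"].abs() > max_tlen
    bad_clip = records["soft_clip"] > max_soft_clip
    bad_mm = records["mismatches"] > 0
    removed = {
        "template_length": int(bad_tlen.sum()),
        "soft_clip": int(bad_clip.sum()),
        "mismatch": int(bad_mm.sum()),
    }
    kept = records[~(bad_tlen | bad_clip | bad_mm)].copy()
    return kept, removed


def umi_proximity_dedup(
    records: pd.DataFrame, window_records: int = 100_000
) -> pd.DataFrame:
    """Keep the first record of each UMI within a sliding record window.

    Input must be position-sorted (within chromosome). Every occurrence of a
    UMI refreshes its window, so chains of nearby duplicates collapse to the
    first record.
    """
    for col in ("chrom", "pos", "umi"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    for _, grp in records.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError("records must be position-sorted within chromosome")
    last_seen: dict[str, int] = {}
    keep = np.ones(len(records), dtype=bool)
    for i, umi in enumerate(records["umi"].tolist()):
        prev = last_seen.get(umi)
        if prev is not None and i - prev <= window_records:
            keep[i] = False
        last_seen[umi] = i
    return records[keep].copy()


# -------------------------------------------------------------------------
# Power-law normalization
# -------------------------------------------------------------------------


def _reference_intercept(cfg: PowerLawConfig) -> float:
    """Scale C of the reference law revcum(x) = C * x**(1 - alpha) with total T.

    The total tag count implied by the law (sum of the reverse cumulative over
    integer counts, continuous approximation) is matched to cfg.total.
    """
    beta = cfg.alpha - 1.0

    def total(C: float) -> float:
        xmax = C ** (1.0 / beta)
        if abs(1.0 - beta) < 1e-9:
            return C * np.log(xmax)
        return C * (xmax ** (1.0 - beta) - 1.0) / (1.0 - beta)

    return float(optimize.brentq(lambda C: total(C) - cfg.total, 1.0 + 1e-9, 1e9))


def powerlaw_normalize(
    counts: np.ndarray, cfg: PowerLawConfig = PowerLawConfig()
) -> np.ndarray:
    """Map raw per-position counts onto a reference power-law distribution.

    Fits log(reverse cumulative count) against log(count) for counts within
    ``fit_range``, then maps each raw count to the value it would take under
    a reference law with exponent -alpha scaled to ``total`` tags. The
    mapping is monotone non-decreasing; zero counts stay zero. Falls back to
    simple scaling (with a warning) when the fit is degenerate.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    positive = counts[counts > 0]
    out = np.zeros_like(counts)
    if positive.size == 0:
        return out
    lo, hi = cfg.fit_range
    vals = np.unique(positive)
    fit_vals = vals[(vals >= lo) & (vals <= hi)]
    if fit_vals.size < 2:
        warnings.warn("fewer than 2 distinct counts in fit range; scaling to total")
        out[counts > 0] = positive * (cfg.total / positive.sum())
        return out
    revcum = np.array([(positive >= v).sum() for v in fit_vals], dtype=float)
    b, a = np.polyfit(np.log(fit_vals), np.log(revcum), 1)
    if b >= 0:
        warnings.warn("non-decreasing reverse cumulative fit; scaling to total")
        out[counts > 0] = positive * (cfg.total / positive.sum())
        return out
    logC = np.log(_reference_intercept(cfg))
    # invert the reference law at the fitted reverse cumulative value
    out[counts > 0] = np.exp((a + b * np.log(positive) - logC) / (1.0 - cfg.alpha))
    return out


# -------------------------------------------------------------------------
# Tag clustering
# -------------------------------------------------------------------------


def _sample_columns(ctss: pd.DataFrame) -> list[str]:
    return [c for c in ctss.columns if c not in ("chrom", "pos", "strand")]


def distclu(
    ctss: pd.DataFrame,
    cfg: PeakCallConfig = PeakCallConfig(),
    min_samples: int = 1,
) -> list[TagCluster]:
    """Distance-based clustering of pass-threshold TSS positions.

    ``ctss`` holds columns (chrom, pos, strand) plus one normalized-signal
    column per sample. Positions whose signal reaches ``cfg.threshold`` in at
    least ``min_samples`` samples seed clusters; same-strand seeds within
    ``cfg.max_dist`` bp are single-linkage merged. Single-position clusters
    are removed unless their signal (max across samples) exceeds
    ``cfg.keep_singletons_above``.
    """
    samples = _sample_columns(ctss)
    if not samples:
        raise ValueError("ctss has no sample columns")
    passing = (ctss[samples] >= cfg.threshold).sum(axis=1) >= min_samples
    seeds = ctss[passing]
    clusters: list[TagCluster] = []
    for (chrom, strand), grp in seeds.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > cfg.max_dist) + 1
        for chunk in np.split(np.arange(len(pos)), breaks):
            members = grp.iloc[chunk]
            cl = TagCluster(
                chrom=chrom,
                strand=strand,
                start=int(members["pos"].min()),
                end=int(members["pos"].max()) + 1,
                positions=tuple(int(p) for p in members["pos"]),
                sample_signal={s: float(members[s].sum()) for s in samples},
            )
            if len(cl.positions) == 1:
                peak_signal = max(float(members[s].max()) for s in samples)
                if not peak_signal > cfg.keep_singletons_above:
                    continue
            clusters.append(cl)
    return clusters


def two_step_peaks(
    ctss: pd.DataFrame,
    cfg: PeakCallConfig = PeakCallConfig(),
    allowlist: list[tuple[str, int, int, str]] = (),
) -> list[TagCluster]:
    """Two-pass peak calling: loose seeds confirmed by a strict pass.

    The loose pass clusters positions passing the threshold in any sample;
    the strict pass requires every sample. A loose cluster is accepted when
    it overlaps (>= 1 bp, same strand) a strict cluster, or an allowlisted
    region (chrom, start, end, strand) for condition-specific promoters that
    only carry signal in a sample subset. Boundaries always come from the
    loose pass.
    """
    n_samples = len(_sample_columns(ctss))
    loose = distclu(ctss, cfg, min_samples=1)
    strict = distclu(ctss, cfg, min_samples=n_samples)
    accepted = []
    for cl in loose:
        confirmed = any(cl.overlaps(s) for s in strict)
        exempt = any(
            cl.chrom == chrom
            and cl.strand == strand
            and cl.start < end
            and start < cl.end
            for chrom, start, end, strand in allowlist
        )
        if confirmed or exempt:
            accepted.append(cl)
    return accepted


def cap_filter(
    clusters: list[TagCluster], min_fraction: float = 0.70
) -> list[TagCluster]:
    """Retain clusters whose fraction of cap-signature reads is > min_fraction.

    The cap signature is at least one reference-unencoded G at the read's
    5' end, left by template switching on a capped transcript. Clusters with
    no reads are removed with a warning.
    """
    kept = []
    for cl in clusters:
        if cl.n_reads == 0:
            warnings.warn(
                f"cluster {cl.chrom}:{cl.start}-{cl.end}({cl.strand}) has no reads"
            )
            continue
        if cl.cap_fraction > min_fraction:
            kept.append(cl)
    return kept


# -------------------------------------------------------------------------
# CAGE vs chromatin signal correlation
# -------------------------------------------------------------------------


def promoter_signal_correlation(
    cage_values: np.ndarray,
    atac_values: np.ndarray,
    atac_total: float = 100_000.0,
    pseudocount: float = 0.0,
) -> tuple[pd.DataFrame, float, float]:
    """Correlate per-peak CAGE signal with matched ATAC signal on log2 scales.

    ATAC values are rescaled to sum to ``atac_total`` across the used peaks;
    both axes are log2-transformed (with the configured pseudocount) and the
    Pearson correlation with its two-tailed t-test p-value is returned.
    """
    cage = np.asarray(cage_values, dtype=float)
    atac = np.asarray(atac_values, dtype=float)
    if cage.shape != atac.shape or cage.ndim != 1:
        raise ValueError("cage and atac vectors must be 1-D and equally long")
    if cage.size < 3:
        raise ValueError("need at least 3 peaks")
    atac_scaled = atac * (atac_total / atac.sum())
    if np.any(cage + pseudocount <= 0) or np.any(atac_scaled + pseudocount <= 0):
        raise ValueError("non-positive values; use a positive pseudocount")
    x = np.log2(cage + pseudocount)
    y = np.log2(atac_scaled + pseudocount)
    r, p = stats.pearsonr(x, y)
    table = pd.DataFrame(
        {"cage": cage, "atac_normalized": atac_scaled, "log2_cage": x, "log2_atac": y}
    )
    return table, float(r), float(p)
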