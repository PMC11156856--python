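"""Binned contact matrices: VC normalization, hotspots, matched backgrounds.

Capture Hi-C contact matrices are corrected with vanilla-coverage (VC)
normalization — dividing each contact by the product of its anchors'
coverage factors — and interaction strength is quantified as the mean
normalized frequency inside a hotspot rectangle versus its surrounding
neighborhood frame.

Whether a set of foreground interactions (e.g. all MAP-MAP pairs) is
enriched is judged against matched backgrounds: for each foreground, the k
candidate interactions at a similar genomic distance (within 5 kb) whose
anchor coverages are nearest in the 2-D coverage space. Coverage profiles
from multiple samples are each scaled to a common sum (100 000) and
averaged before matching, so background selection is not driven by any one
sample's depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .coexpr import fdr_adjust


@dataclass
class ContactMatrix:
    """Symmetric raw contact counts over equally sized bins."""

    region: str
    bin_size: int
    counts: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.counts.shape[0]
        if self.counts.shape != (n, n):
            raise ValueError("contact matrix must be square")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be >= 0")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class Hotspot:
    """Inner rectangle of bin pairs plus the frame around it (the neighborhood)."""

    inner: tuple[int, int, int, int]  # (row_start, row_end, col_start, col_end)
    outer: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        ir0, ir1, ic0, ic1 = self.inner
        or0, or1, oc0, oc1 = self.outer
        if not (or0 <= ir0 < ir1 <= or1 and oc0 <= ic0 < ic1 <= oc1):
            raise ValueError("inner rectangle must lie within the outer rectangle")
        if (or0, or1, oc0, oc1) == (ir0, ir1, ic0, ic1):
            raise ValueError("outer rectangle must strictly contain the inner one")


@dataclass(frozen=True)
class CandidateInteraction:
    anchor_i: int
    anchor_j: int
    bin_size: int

    def __post_init__(self) -> None:
        if self.anchor_i > self.anchor_j:
            raise ValueError("anchors must satisfy i <= j")

    @property
    def genomic_distance(self) -> int:
        return (self.anchor_j - self.anchor_i) * self.bin_size


def vc_normalize(m: ContactMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Vanilla-coverage normalization.

    The coverage profile is the vector of raw row sums; each bin's factor is
    its row sum divided by the mean positive row sum (so a matrix with
    uniform coverage is a fixed point), and normalized(i, j) =
    raw(i, j) / (v_i * v_j). Bins with zero coverage are masked (NaN).
    Returns (normalized matrix, coverage profile).
    """
    coverage = m.counts.sum(axis=0)
    positive = coverage[coverage > 0]
    if positive.size == 0:
        raise ValueError("contact matrix is all zero")
    v = coverage / positive.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = m.counts / np.outer(v, v)
    normalized[coverage == 0, :] = np.nan
    normalized[:, coverage == 0] = np.nan
    return normalized, coverage


def hotspot_strength(normalized: np.ndarray, h: Hotspot) -> tuple[float, float]:
    """Mean normalized frequency inside the hotspot and in its neighborhood."""
    n = normalized.shape[0]
    or0, or1, oc0, oc1 = h.outer
    if not (0 <= or0 and or1 <= n and 0 <= oc0 and oc1 <= n):
        raise ValueError("outer rectangle extends beyond the matrix")
    ir0, ir1, ic0, ic1 = h.inner
    mask_inner = np.zeros((n, n), dtype=bool)
    mask_inner[ir0:ir1, ic0:ic1] = True
    mask_outer = np.zeros((n, n), dtype=bool)
    mask_outer[or0:or1, oc0:oc1] = True
    mask_neigh = mask_outer & ~mask_inner
    inner_vals = normalized[mask_inner]
    neigh_vals = normalized[mask_neigh]
    neigh_vals = neigh_vals[~np.isnan(neigh_vals)]
    inner_vals = inner_vals[~np.isnan(inner_vals)]
    if neigh_vals.size == 0:
        raise ValueError("hotspot neighborhood is empty")
    return float(inner_vals.mean()), float(neigh_vals.mean())


def normalize_coverage_profiles(
    profiles: list[np.ndarray], target: float = 100_000.0
) -> tuple[list[np.ndarray], np.ndarray]:
    """Scale each sample's coverage profile to a common sum; return the mean."""
    scaled = []
    for i, p in enumerate(profiles):
        p = np.asarray(p, dtype=float)
        s = p.sum()
        if s <= 0:
            raise ValueError(f"coverage profile {i} has non-positive sum")
        scaled.append(p * (target / s))
    return scaled, np.mean(scaled, axis=0)


def matched_background(
    fg: CandidateInteraction,
    candidates: list[CandidateInteraction],
    coverage: np.ndarray,
    k: int = 10,
    distance_tolerance: int = 5000,
    exclude: set[tuple[int, int]] = frozenset(),
) -> list[CandidateInteraction]:
    """Select the k best coverage-matched backgrounds at a similar distance.

    Eligible candidates lie within ``distance_tolerance`` of the foreground's
    genomic distance (inclusive) and are neither the foreground itself nor in
    the declared foreground set. They are ranked by Euclidean distance in the
    2-D space of (centromeric anchor coverage, telomeric anchor coverage),
    with deterministic tie-breaking by distance difference then anchor
    indices.
    """
    coverage = np.asarray(coverage, dtype=float)
    fg_key = (fg.anchor_i, fg.anchor_j)
    fg_cov = np.array([coverage[fg.anchor_i], coverage[fg.anchor_j]])
    eligible = []
    for cand in candidates:
        key = (cand.anchor_i, cand.anchor_j)
        if key == fg_key or key in exclude:
            continue
        dist_diff = abs(cand.genomic_distance - fg.genomic_distance)
        if dist_diff > distance_tolerance:
            continue
        cov = np.array([coverage[cand.anchor_i], coverage[cand.anchor_j]])
        eligible.append((float(np.linalg.norm(cov - fg_cov)), dist_diff, key, cand))
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} eligible background candidates; {k} required"
        )
    eligible.sort(key=lambda e: (e[0], e[1], e[2]))
    return [cand for _, _, _, cand in eligible[:k]]


def all_candidate_interactions(
    n_bins: int, bin_size: int, masked: set[int] = frozenset()
) -> list[CandidateInteraction]:
    """Every bin pair (i <= j) in the region, excluding masked bins."""
    return [
        CandidateInteraction(i, j, bin_size)
        for i in range(n_bins)
        if i not in masked
        for j in range(i, n_bins)
        if j not in masked
    ]


def aggregate_pair_profiles(
    anchors: list[int],
    normalized: np.ndarray,
    window_bins: int = 5,
) -> np.ndarray:
    """Average window x window profile over all unordered anchor pairs.

    For each pair the centromeric (smaller-index) anchor indexes rows and the
    telomeric anchor columns; the (2w+1) x (2w+1) submatrix centered on the
    pair is extracted and averaged elementwise. Pairs whose window extends
    off-matrix are skipped with a warning.
    """
    n = normalized.shape[0]
    w = window_bins
    profiles = []
    for idx, a in enumerate(anchors):
        for b in anchors[idx + 1 :]:
            i, j = (a, b) if a <= b else (b, a)
            if i - w < 0 or i + w + 1 > n or j - w < 0 or j + w + 1 > n:
                warnings.warn(f"window around pair ({i}, {j}) extends off-matrix")
                continue
            profiles.append(normalized[i - w : i + w + 1, j - w : j + w + 1])
    if not profiles:
        raise ValueError("no anchor pair has a full window inside the matrix")
    return np.nanmean(np.stack(profiles), axis=0)


def enrichment_test(
    fg_values: np.ndarray, bg_values: np.ndarray
) -> tuple[float, float]:
    """Welch two-sample t-test (two-tailed) of foreground vs background."""
    fg = np.asarray(fg_values, dtype=float)
    bg = np.asarray(bg_values, dtype=float)
    if fg.size < 2 or bg.size < 2:
        raise ValueError("need at least 2 values per group")
    if fg.std() == 0 and bg.std() == 0 and fg.mean() == bg.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(fg, bg, equal_var=False)
    return float(t), float(p)


def enrichment_family(
    tests: list[tuple[np.ndarray, np.ndarray]]
) -> list[tuple[float, float, float]]:
    """Run a family of enrichment tests with BH adjustment across them."""
    raw = [enrichment_test(fg, bg) for fg, bg in tests]
    fdr = fdr_adjust(np.array([p for _, p in raw]))
    return [(t, p, float(q)) for (t, p), q in zip(raw, fdr)]
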