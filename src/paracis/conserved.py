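"""Conserved elements, PWM motif scanning and homology detection.

Highly conserved elements are runs of MSA columns (>= 10 bp) where >= 90% of
the paralogs carry the identical nucleotide; gaps count in the denominator
but are never the conserved character. Elements are scanned with a position
weight matrix using log-odds scores whose p-values are exact: the null score
distribution of a random background k-mer is computed by dynamic programming
over a discretized score grid, so p = P(score >= observed) carries no
sampling error.

Pairwise conservation is summarized VISTA-style — percent identity in a
sliding window (default 100 bp, gaps count as mismatches), highlighting
regions longer than 100 bp above 70% — and homology between two sequences
(direct or inverted) is detected by ungapped seed-and-extend, reporting
segments of at least ``min_len`` bp and ``min_identity``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .msa import GAP, MultipleAlignment

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# -------------------------------------------------------------------------
# Column identity and conserved runs
# -------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnIdentityProfile:
    modal: np.ndarray  # '<U1' modal nucleotide per column ('' if none)
    frequency: np.ndarray  # modal nucleotide frequency, gaps in denominator


@dataclass(frozen=True)
class ConservedElement:
    start: int  # column interval, 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def column_identity(msa: MultipleAlignment) -> ColumnIdentityProfile:
    """Per column: the modal nucleotide and its frequency among all rows.

    Gaps count in the denominator and can never be the modal character, so a
    column of 9 A's and one gap in 10 rows scores 0.9.
    """
    arr = msa.to_array()
    n_rows = arr.shape[0]
    modal = np.empty(msa.n_columns, dtype="<U1")
    freq = np.zeros(msa.n_columns)
    for j in range(msa.n_columns):
        col = arr[:, j]
        best_char, best_n = "", 0
        for b in _BASES:
            n = int((col == b).sum())
            if n > best_n:
                best_char, best_n = b, n
        modal[j] = best_char
        freq[j] = best_n / n_rows
    return ColumnIdentityProfile(modal=modal, frequency=freq)


def conserved_runs(
    profile: ColumnIdentityProfile, min_len: int = 10, min_frac: float = 0.9
) -> list[ConservedElement]:
    """Maximal runs of columns with modal frequency >= min_frac, length >= min_len."""
    passing = profile.frequency >= min_frac
    elements = []
    start = None
    for j, ok in enumerate(np.append(passing, False)):
        if ok and start is None:
            start = j
        elif not ok and start is not None:
            if j - start >= min_len:
                elements.append(ConservedElement(start, j))
            start = None
    return elements


def element_consensus(msa: MultipleAlignment, element: ConservedElement) -> str:
    """Modal-character sequence of a conserved element's columns."""
    profile = column_identity(msa)
    return "".join(profile.modal[element.start : element.end])


# -------------------------------------------------------------------------
# PWM scanning with exact p-values
# -------------------------------------------------------------------------


@dataclass(frozen=True)
class PWM:
    """Position probability matrix over A, C, G, T with a background model."""

    motif_id: str
    probs: np.ndarray  # (k, 4)
    background: np.ndarray  # (4,)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must have shape (k, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0):
            raise ValueError("PWM rows must sum to 1")
        if not np.allclose(bg.sum(), 1.0):
            raise ValueError("background must sum to 1")
        if np.any(probs <= 0) or np.any(bg <= 0):
            raise ValueError("probabilities must be strictly positive (apply a pseudocount)")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.01,
        background: np.ndarray | None = None,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(motif_id, probs, bg)

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.probs[::-1, ::-1], self.background[::-1])

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int  # 0-based on the forward strand
    strand: str
    score: float
    p_value: float


def score_distribution(
    pwm: PWM, granularity: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the discretized log-odds score.

    Scores are discretized to integer multiples of ``granularity`` and the
    distribution of a random background k-mer's total score is built by
    convolving the per-position score distributions. Returns
    (integer score grid offsets, probabilities).
    """
    int_scores = np.round(pwm.log_odds / granularity).astype(np.int64)
    # point mass at score 0, then one convolution per motif position
    dist = np.array([1.0])
    offset = 0
    for k in range(len(pwm)):
        smin = int(int_scores[k].min())
        smax = int(int_scores[k].max())
        new = np.zeros(len(dist) + smax - smin)
        for b in range(4):
            s = int(int_scores[k, b]) - smin
            new[s : s + len(dist)] += dist * pwm.background[b]
        dist = new
        offset += smin
    grid = np.arange(offset, offset + len(dist))
    return grid, dist


def pwm_scan(
    sequence: str,
    pwm: PWM,
    p_cutoff: float = 0.01,
    both_strands: bool = True,
    sequence_id: str = "seq",
    granularity: float = 1e-3,
) -> list[MotifHit]:
    """Scan a sequence with a PWM, reporting hits with exact p < p_cutoff.

    The p-value of a score is the exact probability that a random k-mer drawn
    from the background distribution scores at least as high, computed from
    the discretized null distribution (the observed score is discretized on
    the same grid, so boundary scores are handled consistently).
    """
    seq = sequence.upper()
    k = len(pwm)
    if len(seq) < k:
        return []
    grid, dist = score_distribution(pwm, granularity)
    tail = np.cumsum(dist[::-1])[::-1]  # P(score >= grid value)
    int_scores = np.round(pwm.log_odds / granularity).astype(np.int64)
    base_index = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        base_index[ord(b)] = i
    encoded = base_index[np.frombuffer(seq.encode(), dtype=np.uint8)]
    hits: list[MotifHit] = []
    strands = [("+", pwm, int_scores)]
    if both_strands:
        rc = pwm.reverse_complement()
        strands.append(("-", rc, np.round(rc.log_odds / granularity).astype(np.int64)))
    for strand, mat, ints in strands:
        for off in range(len(seq) - k + 1):
            window = encoded[off : off + k]
            if np.any(window < 0):  # N or other ambiguity: not scored
                continue
            s_int = int(ints[np.arange(k), window].sum())
            idx = np.searchsorted(grid, s_int)
            p = float(tail[idx]) if idx < len(grid) else 0.0
            p = max(p, np.nextafter(0, 1))
            if p < p_cutoff:
                hits.append(
                    MotifHit(
                        sequence_id=sequence_id,
                        offset=off,
                        strand=strand,
                        score=float(s_int * granularity),
                        p_value=p,
                    )
                )
    return hits


def read_jaspar_pfm(path) -> PWM:
    """Read a JASPAR-style position frequency matrix (4 rows: A, C, G, T)."""
    motif_id = "motif"
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                motif_id = line[1:].split()[0]
                continue
            cleaned = line.split("[", 1)[-1].rsplit("]", 1)[0]
            parts = cleaned.replace("A", "").replace("C", "").replace("G", "").replace("T", "").split()
            rows.append([float(x) for x in parts])
    if len(rows) != 4:
        raise ValueError(f"expected 4 nucleotide rows, got {len(rows)}")
    counts = np.array(rows).T  # (k, 4)
    return PWM.from_counts(motif_id, counts)


# -------------------------------------------------------------------------
# Sliding-window identity (VISTA-style)
# -------------------------------------------------------------------------


@dataclass(frozen=True)
class IdentityRegion:
    start: int  # alignment-column interval, half-open
    end: int
    mean_identity: float


def window_identity(
    alignment: MultipleAlignment, window: int = 100
) -> tuple[np.ndarray, list[IdentityRegion]]:
    """Percent identity of a pairwise alignment in a sliding window.

    Gap columns count as mismatches. Each alignment column is assigned the
    identity of the window centered on it (edge columns inherit the nearest
    full window). Maximal runs longer than ``window`` bp with identity
    strictly above 70% are reported as highlighted regions.
    """
    if len(alignment.rows) != 2:
        raise ValueError("window_identity expects a pairwise alignment")
    a, b = (seq for _, seq in alignment.rows)
    L = alignment.n_columns
    match = np.array(
        [1.0 if (x == y and x != GAP) else 0.0 for x, y in zip(a, b)]
    )
    if L < window:
        warnings.warn("alignment shorter than window; using one whole-length window")
        pct = np.full(L, 100.0 * match.mean())
    else:
        sums = np.convolve(match, np.ones(window), mode="valid")
        win_pct = 100.0 * sums / window  # identity of window starting at s
        centers = np.clip(np.arange(L) - window // 2, 0, L - window)
        pct = win_pct[centers]
    regions = []
    above = pct > 70.0
    start = None
    for j, ok in enumerate(np.append(above, False)):
        if ok and start is None:
            start = j
        elif not ok and start is not None:
            if j - start > window:
                regions.append(IdentityRegion(start, j, float(pct[start:j].mean())))
            start = None
    return pct, regions


# -------------------------------------------------------------------------
# Direct / inverted homology search
# -------------------------------------------------------------------------


@dataclass(frozen=True)
class HomologyRegion:
    a_start: int
    a_end: int
    b_start: int  # on the original strand of b
    b_end: int
    strand: str  # '+' direct, '-' inverted
    identity: float

    @property
    def length(self) -> int:
        return self.a_end - self.a_start


def _seed_extend(
    a: str, b: str, seed_len: int, xdrop: int
) -> list[tuple[int, int, int, int, float]]:
    """Ungapped seed-and-extend hits as (a_start, a_end, b_start, b_end, identity)."""
    index: dict[str, list[int]] = {}
    for j in range(len(b) - seed_len + 1):
        index.setdefault(b[j : j + seed_len], []).append(j)
    covered: dict[int, int] = {}  # diagonal -> rightmost a-position covered
    hits = []
    for i in range(len(a) - seed_len + 1):
        for j in index.get(a[i : i + seed_len], ()):
            diag = i - j
            if covered.get(diag, -1) >= i:
                continue
            # extend left
            best, score = 0, 0
            li = 0
            step = 1
            while i - step >= 0 and j - step >= 0:
                score += 1 if a[i - step] == b[j - step] else -1
                if score > best:
                    best, li = score, step
                if score < best - xdrop:
                    break
                step += 1
            # extend right from the seed end
            best, score = 0, 0
            ri = 0
            step = 0
            while i + seed_len + step < len(a) and j + seed_len + step < len(b):
                score += 1 if a[i + seed_len + step] == b[j + seed_len + step] else -1
                if score > best:
                    best, ri = score, step + 1
                if score < best - xdrop:
                    break
                step += 1
            a0, a1 = i - li, i + seed_len + ri
            b0 = j - li
            matches = sum(1 for x, y in zip(a[a0:a1], b[b0 : b0 + (a1 - a0)]) if x == y)
            identity = matches / (a1 - a0)
            covered[diag] = max(covered.get(diag, -1), a1 - 1)
            hits.append((a0, a1, b0, b0 + (a1 - a0), identity))
    return hits


def _chain_diagonal(
    a: str, b: str, hits: list[tuple[int, int, int, int, float]], max_gap: int
) -> list[tuple[int, int, int, int, float]]:
    """Merge collinear ungapped hits on the same diagonal within max_gap bp."""
    by_diag: dict[int, list[tuple[int, int, int, int, float]]] = {}
    for h in hits:
        by_diag.setdefault(h[0] - h[2], []).append(h)
    merged = []
    for diag, group in by_diag.items():
        group.sort()
        cur_a0, cur_a1 = group[0][0], group[0][1]
        for h in group[1:]:
            if h[0] - cur_a1 <= max_gap:
                cur_a1 = max(cur_a1, h[1])
            else:
                merged.append((cur_a0, cur_a1, diag))
                cur_a0, cur_a1 = h[0], h[1]
        merged.append((cur_a0, cur_a1, diag))
    out = []
    for a0, a1, diag in merged:
        b0 = a0 - diag
        matches = sum(1 for x, y in zip(a[a0:a1], b[b0 : b0 + (a1 - a0)]) if x == y)
        out.append((a0, a1, b0, b0 + (a1 - a0), matches / (a1 - a0)))
    return out


def _maximal_extension(
    a: str,
    b: str,
    a0: int,
    a1: int,
    diag: int,
    min_identity: float,
    lookahead: int = 50,
) -> tuple[int, int, float]:
    """Grow [a0, a1) along its diagonal while identity stays >= min_identity.

    An extension is taken only when the added stretch itself meets the
    identity threshold, so a high-identity core is not diluted by random
    flanking sequence; the result is maximal in the sense that no qualifying
    extension within the lookahead remains.
    """
    lo = max(0, diag)  # smallest a-position with a valid b partner
    hi = min(len(a), len(b) + diag)
    matches = sum(1 for x, y in zip(a[a0:a1], b[a0 - diag : a1 - diag]) if x == y)
    improved = True
    while improved:
        improved = False
        run_m, best = matches, None
        for e in range(a1, min(hi, a1 + lookahead)):
            run_m += a[e] == b[e - diag]
            chunk_ok = (run_m - matches) / (e + 1 - a1) >= min_identity
            if chunk_ok and run_m / (e + 1 - a0) >= min_identity:
                best = (e + 1, run_m)
        if best is not None:
            a1, matches = best
            improved = True
        run_m, best = matches, None
        for s in range(a0 - 1, max(lo, a0 - lookahead) - 1, -1):
            run_m += a[s] == b[s - diag]
            chunk_ok = (run_m - matches) / (a0 - s) >= min_identity
            if chunk_ok and run_m / (a1 - s) >= min_identity:
                best = (s, run_m)
        if best is not None:
            a0, matches = best
            improved = True
    return a0, a1, matches / (a1 - a0)


def _longest_qualifying(
    a: str, b: str, diag: int, w0: int, w1: int, min_identity: float
) -> tuple[int, int, float] | None:
    """Longest segment within [w0, w1) on a diagonal with identity >= threshold.

    Linear-time longest-subarray-with-mean >= t on the match indicator:
    transform matches to (1 - t) and mismatches to (-t); the longest
    qualifying segment is the longest span with non-negative sum.
    """
    w0 = max(w0, 0, diag)
    w1 = min(w1, len(a), len(b) + diag)
    if w1 - w0 <= 0:
        return None
    x = np.fromiter(
        ((1.0 - min_identity) if a[i] == b[i - diag] else -min_identity
         for i in range(w0, w1)),
        dtype=float,
        count=w1 - w0,
    )
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix_min = np.minimum.accumulate(prefix)
    # for each end i, the earliest valid start is the first index whose
    # prefix is <= prefix[i]; binary search on the running-min envelope
    best_len, best = 0, None
    for i in range(1, len(prefix)):
        lo_idx, hi_idx = 0, i - 1
        if prefix_min[hi_idx] > prefix[i] + 1e-12:
            continue
        while lo_idx < hi_idx:
            mid = (lo_idx + hi_idx) // 2
            if prefix_min[mid] <= prefix[i] + 1e-12:
                hi_idx = mid
            else:
                lo_idx = mid + 1
        start = lo_idx
        if i - start > best_len:
            best_len, best = i - start, (w0 + start, w0 + i)
    if best is None:
        return None
    s, e = best
    matches = sum(1 for i in range(s, e) if a[i] == b[i - diag])
    return s, e, matches / (e - s)


def homology_search(
    seq_a: str,
    seq_b: str,
    min_len: int = 100,
    min_identity: float = 0.60,
    search_inverted: bool = True,
    seed_len: int = 6,
    xdrop: int = 25,
    max_chain_gap: int = 30,
) -> list[HomologyRegion]:
    """Detect direct and inverted homologous segments between two sequences.

    Ungapped seed-and-extend (exact ``seed_len``-mer seeds, +1/-1 scoring,
    x-drop termination) followed by chaining of collinear hits on the same
    diagonal within ``max_chain_gap`` bp; segments with length >= min_len and
    identity >= min_identity are reported. Inverted homology is searched
    against the reverse complement of ``seq_b``; its coordinates are reported
    on b's original strand.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a, b = seq_a.upper(), seq_b.upper()
    def _qualify(target: str, a0: int, a1: int, diag: int):
        """Extend a chained core; rescue short cores with the exact scan."""
        e0, e1, identity = _maximal_extension(a, target, a0, a1, diag, min_identity)
        if e1 - e0 >= min_len and identity >= min_identity:
            return e0, e1, identity
        if e1 - e0 < min_len // 2:
            # a short core should not be inflated by chance-matching flanks
            return None
        rescued = _longest_qualifying(
            a, target, diag, a0 - 2 * min_len, a1 + 2 * min_len, min_identity
        )
        if rescued is not None and rescued[1] - rescued[0] >= min_len:
            return rescued
        return None

    regions: list[HomologyRegion] = []
    chained = _chain_diagonal(a, b, _seed_extend(a, b, seed_len, xdrop), max_chain_gap)
    for a0, a1, b0, _, _ in chained:
        hit = _qualify(b, a0, a1, a0 - b0)
        if hit is not None:
            e0, e1, identity = hit
            diag = a0 - b0
            regions.append(HomologyRegion(e0, e1, e0 - diag, e1 - diag, "+", identity))
    if search_inverted:
        rc = reverse_complement(b)
        chained = _chain_diagonal(a, rc, _seed_extend(a, rc, seed_len, xdrop), max_chain_gap)
        for a0, a1, b0, _, _ in chained:
            hit = _qualify(rc, a0, a1, a0 - b0)
            if hit is not None:
                e0, e1, identity = hit
                diag = a0 - b0
                rc0, rc1 = e0 - diag, e1 - diag
                regions.append(
                    HomologyRegion(e0, e1, len(b) - rc1, len(b) - rc0, "-", identity)
                )
    # collapse near-duplicate reports of the same segment (same strand,
    # heavily overlapping on both sequences): keep the highest-identity one
    regions.sort(key=lambda r: (r.strand, r.a_start, -(r.a_end - r.a_start)))
    merged: list[HomologyRegion] = []
    for r in regions:
        if merged:
            m = merged[-1]
            if (
                m.strand == r.strand
                and r.a_start < m.a_end
                and min(m.b_end, r.b_end) - max(m.b_start, r.b_start) > 0
            ):
                if r.identity > m.identity:
                    merged[-1] = r
                continue
        merged.append(r)
    return merged
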