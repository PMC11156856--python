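"""Rescue of multimapping reads among near-identical paralogous target regions.

Short reads from recently duplicated loci often align equally well to several
paralogs and are discarded by MAPQ filters, silencing exactly the regions of
interest. The rescue rule keeps them instead, based on the normalized
alignment score nAS = AS / read_length, where AS is the raw end-to-end
alignment score (0 for a perfect match, negative otherwise):

* every placement with nAS below the cutoff (default -0.1) is dropped;
* if one surviving placement is strictly best, the read is assigned there;
* if several placements tie at the best score, the read is assigned to all
  of them;
* a placement inside the declared target set that scores strictly worse than
  the read's best placement anywhere is never assigned.

Cutoff comparisons are carried out in exact rational arithmetic so that reads
sitting exactly on the boundary (nAS == cutoff) are retained, as the rule's
``>=`` demands, without float round-off artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
from Bio import Align

DEFAULT_CUTOFF = Fraction(-1, 10)


@dataclass(frozen=True)
class ScoringScheme:
    """End-to-end read alignment scoring with affine gaps.

    ``gap_open`` is the cost of the first gapped base (open + extend in
    aligner terms), ``gap_extend`` of each further base. With ``match == 0``
    every alignment score is <= 0 and a perfect read scores exactly 0.
    """

    match: int = 0
    mismatch: int = -6
    gap_open: int = -8
    gap_extend: int = -3

    def aligner(self) -> Align.PairwiseAligner:
        """Glocal aligner: read aligned end-to-end, reference gaps free at ends."""
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        # free end gaps in the query row = unaligned reference flanks
        try:
            a.end_deletion_score = 0
        except AttributeError:  # older attribute name
            a.query_end_gap_score = 0
        return a


@dataclass(frozen=True)
class ScoredAlignment:
    """One candidate placement of a read with its raw alignment score."""

    read_id: str
    region_id: str
    raw_score: int
    read_length: int
    is_primary: bool = False
    inside_target_set: bool = True

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError(f"read_length must be positive, got {self.read_length}")
        if self.raw_score > 0:
            raise ValueError(f"raw alignment score must be <= 0, got {self.raw_score}")


class RescueReason(str, Enum):
    MULTI_EQUAL = "multi_equal"
    UNIQUE_BEST = "unique_best"
    DISCARDED_LOW_SCORE = "discarded_low_score"
    REMOVED_BETTER_ELSEWHERE = "removed_better_elsewhere"


@dataclass(frozen=True)
class RescueDecision:
    read_id: str
    assigned_regions: frozenset[str]
    reason: RescueReason

    def __post_init__(self) -> None:
        has_regions = bool(self.assigned_regions)
        keeps = self.reason in (RescueReason.MULTI_EQUAL, RescueReason.UNIQUE_BEST)
        if has_regions != keeps:
            raise ValueError("assigned_regions must be nonempty iff the read is assigned")


def normalized_score(a: ScoredAlignment) -> float:
    """nAS = AS / read_length, in (-inf, 0]."""
    return a.raw_score / a.read_length


def _as_fraction(cutoff) -> Fraction:
    # str() round-trips short decimal literals like -0.1 exactly.
    if isinstance(cutoff, Fraction):
        return cutoff
    return Fraction(str(cutoff))


def rescue_assign(
    alignments: Iterable[ScoredAlignment],
    cutoff=DEFAULT_CUTOFF,
) -> RescueDecision:
    """Apply the normalized-score rescue rule to all placements of one read.

    The cutoff inequality (nAS >= cutoff) is evaluated as
    ``AS * q >= p * read_length`` with cutoff = p/q in lowest terms, so a read
    scoring exactly the cutoff is retained.
    """
    alignments = list(alignments)
    if not alignments:
        warnings.warn("rescue_assign called with no alignments; read discarded")
        return RescueDecision("", frozenset(), RescueReason.DISCARDED_LOW_SCORE)
    read_ids = {a.read_id for a in alignments}
    if len(read_ids) != 1:
        raise ValueError(f"alignments span multiple reads: {sorted(read_ids)}")
    read_id = read_ids.pop()
    cut = _as_fraction(cutoff)

    # Collapse duplicate placements (secondary/supplementary) to the best one.
    best_per_region: dict[str, ScoredAlignment] = {}
    for a in alignments:
        prev = best_per_region.get(a.region_id)
        if prev is None or a.raw_score > prev.raw_score:
            best_per_region[a.region_id] = a

    survivors = [
        a
        for a in best_per_region.values()
        if a.raw_score * cut.denominator >= cut.numerator * a.read_length
    ]
    if not survivors:
        return RescueDecision(read_id, frozenset(), RescueReason.DISCARDED_LOW_SCORE)

    # Same read, so raw AS ordering and nAS ordering coincide.
    best = max(a.raw_score for a in survivors)
    winners = frozenset(a.region_id for a in survivors if a.raw_score == best)
    in_target = any(
        a.inside_target_set for a in survivors if a.region_id in winners
    )
    if not in_target and any(a.inside_target_set for a in survivors):
        # The read maps somewhere in the target set, but strictly better
        # off-target: the target placements are removed.
        return RescueDecision(
            read_id, frozenset(), RescueReason.REMOVED_BETTER_ELSEWHERE
        )
    if len(winners) == 1:
        return RescueDecision(read_id, winners, RescueReason.UNIQUE_BEST)
    return RescueDecision(read_id, winners, RescueReason.MULTI_EQUAL)


def rescue_all(
    alignments: Iterable[ScoredAlignment], cutoff=DEFAULT_CUTOFF
) -> list[RescueDecision]:
    """Group alignments by read and apply :func:`rescue_assign` to each read."""
    by_read: dict[str, list[ScoredAlignment]] = {}
    for a in alignments:
        by_read.setdefault(a.read_id, []).append(a)
    return [rescue_assign(group, cutoff) for group in by_read.values()]


def merge_with_primary(
    rescued: Iterable[RescueDecision],
    primary_reads: Mapping[str, Iterable[str]],
) -> dict[str, set[str]]:
    """Union rescued assignments with primary-pipeline reads, per region.

    Reads counted by the primary (unique-mapper) pipeline are kept even if the
    rescue pass did not assign them; duplicates by read id are collapsed.
    """
    regions: dict[str, set[str]] = {r: set(ids) for r, ids in primary_reads.items()}
    for d in rescued:
        for region in d.assigned_regions:
            regions.setdefault(region, set()).add(d.read_id)
    return regions


def region_counts(per_region_reads: Mapping[str, set[str]]) -> dict[str, int]:
    return {region: len(ids) for region, ids in per_region_reads.items()}


# --------------------------------------------------------------------------
# Brute-force oracle: full dynamic programming, used only by the test suite.
# --------------------------------------------------------------------------

_ORACLE_MAX_READ = 200
_ORACLE_MAX_CANDIDATES = 32
_NEG = -(10**9)


def dp_alignment_score(
    read: str, reference: str, scoring: ScoringScheme = ScoringScheme()
) -> int:
    """Affine-gap glocal score by explicit Gotoh dynamic programming.

    The read aligns end to end; leading/trailing reference bases are free.
    Independent of the production aligner: plain per-cell recursion.
    """
    n, m = len(read), len(reference)
    match = np.where(
        np.frombuffer(read.encode(), dtype=np.uint8)[:, None]
        == np.frombuffer(reference.encode(), dtype=np.uint8)[None, :],
        float(scoring.match),
        float(scoring.mismatch),
    )
    neg = float(_NEG)
    go, ge = float(scoring.gap_open), float(scoring.gap_extend)
    # States at (i, j): M ends with read[i-1]~ref[j-1]; X ends with a gap in
    # the read (ref base consumed); Y ends with a gap in the reference (read
    # base consumed). Row 0's M = 0 everywhere encodes the free leading
    # reference (glocal: the read is global, the reference is local).
    M = np.zeros(m + 1)
    X = np.full(m + 1, neg)
    Y = np.full(m + 1, neg)
    j_idx = np.arange(m + 1, dtype=float)
    for i in range(n):
        prev_best = np.maximum(M, np.maximum(X, Y))
        Y_new = np.maximum(np.maximum(M, X) + go, Y + ge)
        M_new = np.full(m + 1, neg)
        M_new[1:] = prev_best[:-1] + match[i]
        # X_new[j] = max_{j' < j} F[j'] + go + ge*(j - j' - 1): a running
        # maximum of F[j'] + go - ge*(j'+1), shifted, plus ge*j.
        F = np.maximum(M_new, Y_new)
        g = np.maximum.accumulate(F + go - ge * (j_idx + 1.0))
        X_new = np.full(m + 1, neg)
        X_new[1:] = ge * j_idx[1:] + g[:-1]
        M, X, Y = M_new, X_new, Y_new
    # Trailing reference is free: best over j among alignments whose last
    # column consumed a read base (an X-ending alignment is dominated).
    return int(round(np.max(np.maximum(M, Y))))


def oracle_rescue(
    read: str,
    candidate_regions: Mapping[str, str],
    scoring: ScoringScheme = ScoringScheme(),
    cutoff=DEFAULT_CUTOFF,
    read_id: str = "read",
) -> RescueDecision:
    """Exhaustive-alignment rescue decision for one read (test oracle).

    Scores the read against every candidate region by full dynamic
    programming, then applies :func:`rescue_assign`. Refuses large instances.
    """
    if len(read) > _ORACLE_MAX_READ:
        raise ValueError(f"oracle limited to reads <= {_ORACLE_MAX_READ} bp")
    if len(candidate_regions) > _ORACLE_MAX_CANDIDATES:
        raise ValueError(f"oracle limited to <= {_ORACLE_MAX_CANDIDATES} candidates")
    scored = [
        ScoredAlignment(
            read_id=read_id,
            region_id=region,
            raw_score=min(0, dp_alignment_score(read, seq, scoring)),
            read_length=len(read),
        )
        for region, seq in candidate_regions.items()
    ]
    return rescue_assign(scored, cutoff)
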