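"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the real inputs: a family
of paralogous loci diverged from a common ancestor with planted conserved
cis-regulatory elements, Tn5 insertion events enriched at those elements,
multimapping short reads, binarized single-cell expression matrices with
planted pairwise odds ratios, and distance-decaying Hi-C contact matrices
with coverage biases and planted contact hotspots.

Every generator is deterministic under its seed. Each module draws from its
own RNG stream, derived from the master seed through a fixed spawn key
(see ``STREAMS``), so adding one generator never perturbs another.

The true multiple alignment of the family is built constructively from the
mutation log — never re-estimated by an aligner — so consensus and
projection tests are independent of any alignment heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .msa import GAP, MultipleAlignment
from .rescue import ScoredAlignment, ScoringScheme

NUCLEOTIDES = np.array(list("ACGT"))

#: Fixed spawn keys: one independent RNG stream per generator.
STREAMS = {
    "family": 0,
    "plant": 1,
    "insertions": 2,
    "reads": 3,
    "cells": 4,
    "contacts": 5,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """RNG for one generator stream, derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STREAMS[stream],)))


class FeasibilityError(ValueError):
    """A requested parameter combination admits no valid joint distribution."""


class PlantingError(ValueError):
    """A conserved element cannot be planted at the requested location."""


# =========================================================================
# Paralog family
# =========================================================================


@dataclass(frozen=True)
class Mutation:
    """One event relative to the ancestor.

    ``position`` is in ancestor coordinates. For ``sub`` the payload is the
    replacement base; for ``ins`` the inserted sequence (placed before the
    ancestor base at ``position``); for ``del`` the deleted length.
    """

    paralog: str
    position: int
    kind: str  # "sub" | "ins" | "del"
    payload: str | int


@dataclass(frozen=True)
class PlantedElement:
    name: str
    ancestor_interval: tuple[int, int]  # 0-based half-open, ancestor coords
    column_interval: tuple[int, int]  # same element as true-MSA columns
    carriers: frozenset[str]
    sequence: str


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_paralogs: int = 8
    ancestor_length: int = 2000
    substitution_rate: float = 0.02
    indel_rate: float = 0.002
    indel_length_p: float = 0.5  # geometric parameter; mean length 1/p
    depth: float = 500.0  # expected Tn5 insertions per locus
    hotspot_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.ancestor_length < 1:
            raise ValueError("ancestor_length must be >= 1")
        if self.n_paralogs < 1:
            raise ValueError("n_paralogs must be >= 1")
        for name in ("substitution_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.indel_length_p <= 1.0:
            raise ValueError("indel_length_p must be in (0, 1]")
        if self.depth < 0 or self.hotspot_multiplier < 0:
            raise ValueError("depth and hotspot_multiplier must be >= 0")


@dataclass(frozen=True)
class ParalogFamily:
    ancestor: str
    paralogs: tuple[tuple[str, str], ...]
    true_msa: MultipleAlignment
    mutation_log: tuple[Mutation, ...]
    planted_elements: tuple[PlantedElement, ...] = ()
    #: ancestor position -> true-MSA column index
    ancestor_columns: tuple[int, ...] = ()

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.paralogs]

    def sequence(self, name: str) -> str:
        for n, s in self.paralogs:
            if n == name:
                return s
        raise KeyError(name)

    @property
    def paralog_msa(self) -> MultipleAlignment:
        """True MSA restricted to the paralog rows (ancestor dropped)."""
        return self.true_msa.subset(self.names)


def _draw_mutations(
    name: str, ancestor: str, config: SimulationConfig, rng: np.random.Generator
) -> list[Mutation]:
    L = len(ancestor)
    muts: list[Mutation] = []
    # Deletions first so that substitutions never land on deleted bases.
    deleted = np.zeros(L, dtype=bool)
    if config.indel_rate > 0:
        del_starts = np.flatnonzero(rng.random(L) < config.indel_rate / 2)
        for start in del_starts:
            if deleted[start]:
                continue
            length = int(rng.geometric(config.indel_length_p))
            length = min(length, L - start)
            muts.append(Mutation(name, int(start), "del", length))
            deleted[start : start + length] = True
        ins_points = np.flatnonzero(rng.random(L + 1) < config.indel_rate / 2)
        for point in ins_points:
            length = int(rng.geometric(config.indel_length_p))
            seq = "".join(rng.choice(NUCLEOTIDES, size=length))
            muts.append(Mutation(name, int(point), "ins", seq))
    if config.substitution_rate > 0:
        sub_pos = np.flatnonzero(
            (rng.random(L) < config.substitution_rate) & ~deleted
        )
        for pos in sub_pos:
            old = ancestor[pos]
            choices = [b for b in "ACGT" if b != old]
            muts.append(Mutation(name, int(pos), "sub", str(rng.choice(choices))))
    return muts


def apply_mutations(ancestor: str, muts: list[Mutation]) -> str:
    """Reconstruct a paralog sequence from the ancestor and its log entries."""
    L = len(ancestor)
    base = list(ancestor)
    deleted = np.zeros(L, dtype=bool)
    inserts: dict[int, list[str]] = {}
    for m in muts:
        if m.kind == "sub":
            base[m.position] = str(m.payload)
        elif m.kind == "del":
            deleted[m.position : m.position + int(m.payload)] = True
        elif m.kind == "ins":
            inserts.setdefault(m.position, []).append(str(m.payload))
        else:
            raise ValueError(f"unknown mutation kind {m.kind!r}")
    out: list[str] = []
    for i in range(L + 1):
        for seq in inserts.get(i, ()):
            out.append(seq)
        if i < L and not deleted[i]:
            out.append(base[i])
    return "".join(out)


def _build_true_msa(
    ancestor: str, logs: dict[str, list[Mutation]]
) -> tuple[MultipleAlignment, tuple[int, ...]]:
    """Construct the true MSA (ancestor row first) from per-paralog logs.

    Each ancestor position is one column; each insertion contributes its own
    block of columns carrying gaps in every other row (insertions from
    different paralogs are not aligned to each other).
    """
    L = len(ancestor)
    names = list(logs)
    subs = {n: {} for n in names}
    deleted = {n: np.zeros(L, dtype=bool) for n in names}
    inserts: dict[str, dict[int, list[str]]] = {n: {} for n in names}
    for n, muts in logs.items():
        for m in muts:
            if m.kind == "sub":
                subs[n][m.position] = str(m.payload)
            elif m.kind == "del":
                deleted[n][m.position : m.position + int(m.payload)] = True
            elif m.kind == "ins":
                inserts[n].setdefault(m.position, []).append(str(m.payload))

    rows: dict[str, list[str]] = {"ancestor": []}
    for n in names:
        rows[n] = []
    ancestor_columns: list[int] = []
    n_cols = 0

    def _emit_insertions(point: int) -> None:
        nonlocal n_cols
        for n in names:
            for seq in inserts[n].get(point, ()):
                rows["ancestor"].append(GAP * len(seq))
                for other in names:
                    rows[other].append(seq if other == n else GAP * len(seq))
                n_cols += len(seq)

    for i in range(L):
        _emit_insertions(i)
        ancestor_columns.append(n_cols)
        rows["ancestor"].append(ancestor[i])
        for n in names:
            if deleted[n][i]:
                rows[n].append(GAP)
            else:
                rows[n].append(subs[n].get(i, ancestor[i]))
        n_cols += 1
    _emit_insertions(L)

    msa = MultipleAlignment(
        tuple((name, "".join(parts)) for name, parts in rows.items())
    )
    return msa, tuple(ancestor_columns)


def generate_paralog_family(config: SimulationConfig) -> ParalogFamily:
    """Simulate paralogs diverging from a random common ancestor.

    Substitutions are uniform over the three alternative bases; indel lengths
    are geometric. The returned family carries the full mutation log, the
    constructively built true MSA, and the ancestor-to-column map.
    """
    rng = stream_rng(config.seed, "family")
    ancestor = "".join(rng.choice(NUCLEOTIDES, size=config.ancestor_length))
    logs: dict[str, list[Mutation]] = {}
    for k in range(config.n_paralogs):
        name = f"paralog_{k:02d}"
        logs[name] = _draw_mutations(name, ancestor, config, rng)
    msa, anc_cols = _build_true_msa(ancestor, logs)
    paralogs = tuple((n, apply_mutations(ancestor, logs[n])) for n in logs)
    return ParalogFamily(
        ancestor=ancestor,
        paralogs=paralogs,
        true_msa=msa,
        mutation_log=tuple(m for muts in logs.values() for m in muts),
        ancestor_columns=anc_cols,
    )


def plant_conserved_element(
    family: ParalogFamily,
    element: str,
    carriers: list[str] | None = None,
    decay_rate: float = 0.25,
    position: int | None = None,
    name: str | None = None,
    rng: np.random.Generator | int = 0,
) -> ParalogFamily:
    """Insert a conserved element into the family at a homologous position.

    The element is spliced into the ancestor, so every row gains aligned
    columns at the same place: carriers receive the element verbatim (and no
    pre-existing mutation can fall inside it), non-carriers receive a copy
    decayed by per-base substitutions at ``decay_rate``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = stream_rng(int(rng), "plant")
    if len(element) == 0:
        raise PlantingError("element must be non-empty")
    if len(element) >= len(family.ancestor):
        raise PlantingError("element must be shorter than the ancestor")
    carriers = list(family.names if carriers is None else carriers)
    unknown = set(carriers) - set(family.names)
    if unknown:
        raise PlantingError(f"unknown carrier paralogs: {sorted(unknown)}")

    L = len(family.ancestor)
    Le = len(element)
    occupied = [e.ancestor_interval for e in family.planted_elements]
    if position is None:
        candidates = [
            p
            for p in range(L + 1)
            if not any(s < p < e for s, e in occupied)
        ]
        position = int(rng.choice(candidates))
    if any(s < position < e for s, e in occupied):
        raise PlantingError(
            f"position {position} overlaps a previously planted element"
        )

    new_ancestor = family.ancestor[:position] + element + family.ancestor[position:]

    def shift(m: Mutation) -> list[Mutation]:
        if m.kind == "del":
            start, length = m.position, int(m.payload)
            if start < position < start + length:
                # split a deletion spanning the insertion point
                left = Mutation(m.paralog, start, "del", position - start)
                right = Mutation(
                    m.paralog, position + Le, "del", start + length - position
                )
                return [left, right]
            if start >= position:
                return [replace(m, position=start + Le)]
            return [m]
        if m.position >= position:
            return [replace(m, position=m.position + Le)]
        return [m]

    logs: dict[str, list[Mutation]] = {n: [] for n in family.names}
    for m in family.mutation_log:
        logs[m.paralog].extend(shift(m))
    for n in family.names:
        if n not in carriers and decay_rate > 0:
            decay_pos = np.flatnonzero(rng.random(Le) < decay_rate)
            for p in decay_pos:
                old = element[p]
                choices = [b for b in "ACGT" if b != old]
                logs[n].append(
                    Mutation(n, position + int(p), "sub", str(rng.choice(choices)))
                )

    msa, anc_cols = _build_true_msa(new_ancestor, logs)
    paralogs = tuple((n, apply_mutations(new_ancestor, logs[n])) for n in family.names)
    shifted_elements = tuple(
        replace(
            e,
            ancestor_interval=(
                (e.ancestor_interval[0] + Le, e.ancestor_interval[1] + Le)
                if e.ancestor_interval[0] >= position
                else e.ancestor_interval
            ),
        )
        for e in family.planted_elements
    )
    new_element = PlantedElement(
        name=name or f"element_{len(family.planted_elements)}",
        ancestor_interval=(position, position + Le),
        column_interval=(anc_cols[position], anc_cols[position + Le - 1] + 1),
        carriers=frozenset(carriers),
        sequence=element,
    )
    # column intervals of earlier elements must be recomputed against the new MSA
    shifted_elements = tuple(
        replace(
            e,
            column_interval=(
                anc_cols[e.ancestor_interval[0]],
                anc_cols[e.ancestor_interval[1] - 1] + 1,
            ),
        )
        for e in shifted_elements
    )
    return ParalogFamily(
        ancestor=new_ancestor,
        paralogs=paralogs,
        true_msa=msa,
        mutation_log=tuple(m for n in family.names for m in logs[n]),
        planted_elements=shifted_elements + (new_element,),
        ancestor_columns=anc_cols,
    )


def ancestor_to_paralog_positions(family: ParalogFamily, name: str) -> np.ndarray:
    """Map ancestor positions to ungapped paralog positions (-1 if deleted)."""
    row = np.array(list(family.true_msa.row(name)))
    pos_in_row = np.cumsum(row != GAP) - 1
    cols = np.asarray(family.ancestor_columns)
    out = np.where(row[cols] != GAP, pos_in_row[cols], -1)
    return out.astype(np.int64)


# =========================================================================
# Tn5 insertion events
# =========================================================================


@dataclass(frozen=True)
class InsertionSimulation:
    """Per-paralog, per-sample Tn5 insertion positions plus the true intensities."""

    events: dict[str, list[np.ndarray]]  # paralog -> one position array per sample
    intensities: dict[str, np.ndarray]  # paralog -> per-bp expected event count


def simulate_insertions(
    family: ParalogFamily,
    config: SimulationConfig,
    enrichment_map: dict[str, float] | None = None,
    n_samples: int = 1,
    carriers_only: bool = True,
) -> InsertionSimulation:
    """Draw Tn5 insertion events with enrichment inside planted elements.

    The per-bp intensity is ``depth / locus_length`` times the element's
    multiplier inside planted elements (by default only in carrier paralogs,
    where the element is intact); totals are Poisson.
    """
    enrichment_map = enrichment_map or {}
    for elem, mult in enrichment_map.items():
        if mult < 0:
            raise ValueError(f"multiplier for {elem!r} must be >= 0, got {mult}")
    rng = stream_rng(config.seed, "insertions")
    events: dict[str, list[np.ndarray]] = {}
    intensities: dict[str, np.ndarray] = {}
    elements = {e.name: e for e in family.planted_elements}
    for pname in family.names:
        seq = family.sequence(pname)
        Lp = len(seq)
        lam = np.full(Lp, config.depth / Lp)
        anc_map = ancestor_to_paralog_positions(family, pname)
        for ename, mult in enrichment_map.items():
            e = elements[ename]
            if carriers_only and pname not in e.carriers:
                continue
            s, t = e.ancestor_interval
            targets = anc_map[s:t]
            targets = targets[targets >= 0]
            lam[targets] *= mult
        intensities[pname] = lam
        per_sample = []
        for _ in range(n_samples):
            if lam.sum() <= 0:
                per_sample.append(np.empty(0, dtype=np.int64))
                continue
            n = rng.poisson(lam.sum())
            pos = rng.choice(Lp, size=n, p=lam / lam.sum())
            per_sample.append(np.sort(pos).astype(np.int64))
        events[pname] = per_sample
    return InsertionSimulation(events=events, intensities=intensities)


# =========================================================================
# Multimapping reads
# =========================================================================


@dataclass(frozen=True)
class MultireadSimulation:
    reads: tuple[str, ...]  # read sequences, index = read number
    alignments: tuple[tuple[ScoredAlignment, ...], ...]  # per read, one per paralog
    truth: tuple[tuple[str, int], ...]  # (origin paralog, 0-based start)


def simulate_multireads(
    family: ParalogFamily,
    read_length: int,
    n_reads: int,
    scoring: ScoringScheme = ScoringScheme(),
    seed: int = 0,
    error_rate: float = 0.01,
) -> MultireadSimulation:
    """Draw reads from random paralogs and score them against every paralog.

    Each read is a substring of one paralog with per-base substitution errors
    at ``error_rate``; the emitted score set comes from exhaustive glocal
    alignment of the read against the full sequence of every paralog, so
    every candidate placement is considered.
    """
    shortest = min(len(s) for _, s in family.paralogs)
    if read_length > shortest:
        raise ValueError(
            f"read_length {read_length} exceeds shortest paralog ({shortest} bp)"
        )
    rng = stream_rng(seed, "reads")
    aligner = scoring.aligner()
    reads: list[str] = []
    truth: list[tuple[str, int]] = []
    alignments: list[tuple[ScoredAlignment, ...]] = []
    names = family.names
    for i in range(n_reads):
        origin = names[int(rng.integers(len(names)))]
        seq = family.sequence(origin)
        start = int(rng.integers(len(seq) - read_length + 1))
        read = list(seq[start : start + read_length])
        err_pos = np.flatnonzero(rng.random(read_length) < error_rate)
        for p in err_pos:
            choices = [b for b in "ACGT" if b != read[p]]
            read[p] = str(rng.choice(choices))
        read = "".join(read)
        read_id = f"read_{i:06d}"
        scored = tuple(
            ScoredAlignment(
                read_id=read_id,
                region_id=n,
                raw_score=min(0, int(round(aligner.score(family.sequence(n), read)))),
                read_length=read_length,
            )
            for n in names
        )
        reads.append(read)
        truth.append((origin, start))
        alignments.append(scored)
    return MultireadSimulation(tuple(reads), tuple(alignments), tuple(truth))


# =========================================================================
# Binary cell-by-gene matrices with planted odds ratios
# =========================================================================

#: smallest admissible cell probability in a planted 2x2 joint distribution
MIN_CELL_PROB = 1e-4


def joint_from_odds_ratio(
    px: float, py: float, theta: float, min_cell_prob: float = MIN_CELL_PROB
) -> tuple[float, float, float, float]:
    """Joint (p00, p01, p10, p11) with given marginals and odds ratio.

    Solves the quadratic for p11 (the Plackett construction) and takes the
    root inside the Fréchet bounds [max(0, px+py-1), min(px, py)]. A
    combination whose solution pushes any cell probability below
    ``min_cell_prob`` is rejected as infeasible.
    """
    if not (0 < px < 1 and 0 < py < 1):
        raise FeasibilityError("marginals must lie strictly inside (0, 1)")
    if theta <= 0:
        raise FeasibilityError("target odds ratio must be > 0")
    if theta == 1.0:
        p11 = px * py
    else:
        a = theta - 1.0
        s = 1.0 + (px + py) * a
        disc = s * s - 4.0 * a * theta * px * py
        if disc < 0:
            raise FeasibilityError("no real solution for the joint distribution")
        p11 = (s - np.sqrt(disc)) / (2.0 * a)
    lo, hi = max(0.0, px + py - 1.0), min(px, py)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise FeasibilityError(
            f"p11 = {p11:.3g} outside Fréchet bounds [{lo:.3g}, {hi:.3g}]"
        )
    p10 = px - p11
    p01 = py - p11
    p00 = 1.0 - px - py + p11
    probs = (p00, p01, p10, p11)
    if min(probs) < min_cell_prob:
        raise FeasibilityError(
            f"cell probabilities {probs} below the feasible resolution "
            f"({min_cell_prob}) for marginals ({px}, {py}) and OR {theta}"
        )
    return probs


def simulate_cell_matrix(
    n_cells: int,
    gene_marginals: dict[str, float],
    planted_pairs: list[tuple[str, str, float]] = (),
    seed: int = 0,
):
    """Binary cell-by-gene matrix with planted pairwise odds ratios.

    Genes in a planted pair are drawn jointly from the 2x2 distribution that
    matches their marginals and the target odds ratio; all other genes are
    independent Bernoulli draws. Returns a boolean ``pandas.DataFrame``
    (cells x genes).
    """
    import pandas as pd

    genes = list(gene_marginals)
    planted_genes: set[str] = set()
    for x, y, theta in planted_pairs:
        if x == y:
            raise ValueError("planted pairs must involve two distinct genes")
        if {x, y} & planted_genes:
            raise ValueError("planted pairs must be disjoint in genes")
        planted_genes |= {x, y}
        for g in (x, y):
            if g not in gene_marginals:
                raise KeyError(f"planted gene {g!r} has no marginal")
    rng = stream_rng(seed, "cells")
    data = {}
    for x, y, theta in planted_pairs:
        p00, p01, p10, p11 = joint_from_odds_ratio(
            gene_marginals[x], gene_marginals[y], theta
        )
        draw = rng.choice(4, size=n_cells, p=[p00, p01, p10, p11])
        data[x] = (draw >= 2)  # categories 2 (x+y-) and 3 (x+y+)
        data[y] = (draw % 2 == 1)  # categories 1 (x-y+) and 3 (x+y+)
    for g in genes:
        if g not in planted_genes:
            data[g] = rng.random(n_cells) < gene_marginals[g]
    return pd.DataFrame({g: data[g] for g in genes})


# =========================================================================
# Contact matrices
# =========================================================================


def simulate_contact_matrix(
    n_bins: int,
    bin_size: int,
    decay_exponent: float,
    coverage_biases: np.ndarray,
    hotspots: list[tuple[tuple[int, int, int, int], float]] = (),
    seed: int = 0,
    intensity: float = 100.0,
    region: str = "sim",
    sample_id: str = "sim",
):
    """Symmetric Poisson contact matrix with decay, biases and hotspots.

    Expected count for bins (i, j) is
    ``intensity * c_i * c_j * max(|i-j|, 1) ** (-decay_exponent) * h_ij``
    where h carries the planted hotspot multipliers (applied symmetrically).
    """
    from .hic import ContactMatrix

    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    c = np.asarray(coverage_biases, dtype=float)
    if c.shape != (n_bins,):
        raise ValueError(f"coverage_biases must have shape ({n_bins},)")
    if np.any(c <= 0):
        raise ValueError("coverage biases must be > 0")
    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :])
    mu = intensity * np.outer(c, c) * np.maximum(dist, 1).astype(float) ** (
        -decay_exponent
    )
    h = np.ones((n_bins, n_bins))
    for (r0, r1, c0, c1), mult in hotspots:
        if not (0 <= r0 < r1 <= n_bins and 0 <= c0 < c1 <= n_bins):
            raise ValueError(f"hotspot rectangle {(r0, r1, c0, c1)} outside matrix")
        if mult < 0:
            raise ValueError("hotspot multiplier must be >= 0")
        h[r0:r1, c0:c1] = mult
        h[c0:c1, r0:r1] = mult
    rng = stream_rng(seed, "contacts")
    upper = rng.poisson(np.triu(mu * h))
    counts = np.triu(upper) + np.triu(upper, 1).T
    return ContactMatrix(
        region=region, bin_size=bin_size, counts=counts.astype(float), sample_id=sample_id
    )
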