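"""Binarized single-cell co-expression odds ratios with exact tests.

Stochastic, largely monoallelic expression of a receptor family is summarized
by binarizing each cell-by-gene count matrix ('+' means at least one
pass-filter read) and, for every ordered gene pair (x, y), tabulating cells
into the 2x2 table

    a = x- y-    b = x- y+
    c = x+ y-    d = x+ y+

The odds ratio of y's expression in x+ vs x- cells is (d/c)/(b/a) = ad/bc;
significance comes from Fisher's exact test with Benjamini-Hochberg FDR
adjustment across pairs. When several biological replicates are given, the
reported entry is the mean odds ratio and the least significant (largest)
FDR.

``fisher_exact`` here is a direct implementation of the two-sided
probability-mass definition — the sum of hypergeometric probabilities of all
tables with the observed margins that are no more probable than the observed
one — and is cross-checked in the test suite against an independent exact
enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

#: relative slack when comparing table probabilities (guards float round-off,
#: mirroring the convention of standard exact-test implementations)
_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts: a = x-y-, b = x-y+, c = x+y-, d = x+y+."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cell counts must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ORResult:
    gene_x: str
    gene_y: str
    odds_ratio: float  # may be inf or nan (flagged degenerate forms)
    p_value: float
    fdr: float = float("nan")

    @property
    def defined(self) -> bool:
        return math.isfinite(self.odds_ratio)


def binarize(counts: pd.DataFrame) -> pd.DataFrame:
    """'+' iff at least one read: entry true where count >= 1."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be >= 0")
    return counts >= 1


def all_zero_genes(binary: pd.DataFrame) -> list[str]:
    """QC helper: genes never detected in any cell."""
    return [g for g in binary.columns if not binary[g].any()]


def contingency(binary: pd.DataFrame, x: str, y: str) -> ContingencyTable:
    """2x2 partition of cells by binary expression of genes x and y."""
    if x == y:
        raise ValueError("x and y must be distinct genes")
    for g in (x, y):
        if g not in binary.columns:
            raise KeyError(f"gene {g!r} not in matrix")
    vx = binary[x].to_numpy(dtype=bool)
    vy = binary[y].to_numpy(dtype=bool)
    return ContingencyTable(
        a=int((~vx & ~vy).sum()),
        b=int((~vx & vy).sum()),
        c=int((vx & ~vy).sum()),
        d=int((vx & vy).sum()),
    )


def odds_ratio(t: ContingencyTable) -> float:
    """(d/c)/(b/a) = ad/bc; inf when only bc = 0, nan when both products are 0."""
    ad, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        return float("inf") if ad > 0 else float("nan")
    return ad / bc


def _hypergeom_log_pmf(t: ContingencyTable) -> np.ndarray:
    """Log-probabilities of all tables sharing t's margins, indexed by d."""
    row1 = t.a + t.b  # x- cells
    col1 = t.b + t.d  # y+ cells
    n = t.n
    d = np.arange(max(0, col1 - row1), min(col1, n - row1) + 1)
    b = col1 - d
    a = row1 - b
    c = n - row1 - d
    logp = (
        gammaln(row1 + 1)
        - gammaln(a + 1)
        - gammaln(b + 1)
        + gammaln(n - row1 + 1)
        - gammaln(c + 1)
        - gammaln(d + 1)
        - (gammaln(n + 1) - gammaln(col1 + 1) - gammaln(n - col1 + 1))
    )
    return d, logp


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p: mass of tables no more probable than observed.

    Enumerates every table with the observed margins, computes hypergeometric
    probabilities, and sums those with probability <= that of the observed
    table (within relative tolerance 1e-7).
    """
    if t.n == 0:
        return 1.0
    d_vals, logp = _hypergeom_log_pmf(t)
    p = np.exp(logp - logp.max())
    observed = p[np.flatnonzero(d_vals == t.d)[0]]
    total = p.sum()
    return float(min(1.0, p[p <= observed * (1 + _REL_TOL)].sum() / total))


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_odds_ratios(binary: pd.DataFrame, genes: list[str] | None = None) -> pd.DataFrame:
    """Odds ratio, Fisher p and BH-FDR for every ordered pair of distinct genes.

    FDR adjustment spans all pairs in the returned frame (the declared test
    family). Self-pairs are excluded.
    """
    genes = list(genes if genes is not None else binary.columns)
    rows = []
    for x in genes:
        for y in genes:
            if x == y:
                continue
            t = contingency(binary, x, y)
            rows.append(
                {
                    "gene_x": x,
                    "gene_y": y,
                    "odds_ratio": odds_ratio(t),
                    "p_value": fisher_exact(t),
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                }
            )
    out = pd.DataFrame(rows)
    out["fdr"] = fdr_adjust(out["p_value"].to_numpy())
    return out


def combine_samples(results: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-sample pair tables: mean odds ratio, least significant FDR.

    With more than two samples the rule generalizes to the maximum FDR and the
    arithmetic mean. Pairs with any non-finite odds ratio are flagged and
    their mean withheld.
    """
    if not results:
        raise ValueError("no samples to combine")
    keys = ["gene_x", "gene_y"]
    base = results[0][keys]
    for r in results[1:]:
        if not base.reset_index(drop=True).equals(r[keys].reset_index(drop=True)):
            raise ValueError("samples carry different gene-pair sets")
    ors = np.stack([r["odds_ratio"].to_numpy(dtype=float) for r in results])
    fdrs = np.stack([r["fdr"].to_numpy(dtype=float) for r in results])
    degenerate = ~np.isfinite(ors).all(axis=0)
    mean_or = np.where(degenerate, np.nan, np.nanmean(np.where(np.isfinite(ors), ors, np.nan), axis=0))
    out = base.copy()
    out["odds_ratio_mean"] = mean_or
    out["fdr_max"] = fdrs.max(axis=0)
    out["degenerate"] = degenerate
    return out


def heatmap_matrix(combined: pd.DataFrame, value: str = "odds_ratio_mean") -> pd.DataFrame:
    """Square gene-by-gene matrix of combined entries (rows = x, columns = y)."""
    return combined.pivot(index="gene_x", columns="gene_y", values=value)
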