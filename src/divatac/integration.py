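"""DAR x DML quadrant integration and region-set overlap statistics.

Pairs each differential accessible region with the CpGs it contains and
classifies the (methylation change, accessibility change) plane into
quadrants; Q3 (demethylated, gained accessibility) and Q2 (demethylated,
lost accessibility) are the biologically loaded ones during B-cell
differentiation, where nearly all changing CpGs lose methylation.

Also provides the exact two-sided statistics used throughout: a Fisher
exact test via hypergeometric tail summation, an exact Wilcoxon rank-sum
(full-enumeration) with a tie/continuity-corrected normal approximation for
larger samples, and Welch's t for histone-mark loss between cell states.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm, rankdata, ttest_ind

WILCOXON_EXACT_MAX = 10  # exact enumeration when both samples are <= this


@dataclass(frozen=True)
class OverlapTable:
    """A 2x2 overlap table with Haldane-corrected odds ratio."""

    a: int  # in set, in feature
    b: int  # in set, not in feature
    c: int  # not in set, in feature
    d: int  # not in set, not in feature
    odds_ratio: float
    pvalue: float


def quadrant_of(delta_meth: float, delta_access: float) -> str | None:
    """Quadrant label; None when either delta is exactly zero."""
    if delta_meth == 0 or delta_access == 0:
        return None
    if delta_meth > 0:
        return "Q1" if delta_access > 0 else "Q4"
    return "Q3" if delta_access > 0 else "Q2"


def pair_dar_dml(
    dars: pd.DataFrame, regions: Mapping[str, tuple[str, int, int]],
    dmls: pd.DataFrame,
) -> pd.DataFrame:
    """One row per (DAR, contained CpG) with its quadrant.

    ``dars`` needs columns region_id and log2fc; ``regions`` maps region_id
    to (chrom, start, end); ``dmls`` needs chrom, pos, delta_meth.  CpG
    positions are 1-bp intervals under half-open containment.  Pairs with
    either delta exactly zero are dropped (their count is in the
    ``n_zero_dropped`` attribute of the result).
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in dmls.groupby("chrom"):
        order = np.argsort(sub["pos"].to_numpy())
        by_chrom[str(chrom)] = (
            sub["pos"].to_numpy()[order],
            sub["delta_meth"].to_numpy()[order],
        )
    rows = []
    dropped = 0
    for rec in dars.itertuples():
        chrom, start, end = regions[rec.region_id]
        if chrom not in by_chrom:
            continue
        pos, delta = by_chrom[chrom]
        lo = np.searchsorted(pos, start)
        hi = np.searchsorted(pos, end)  # pos < end: half-open
        for i in range(lo, hi):
            q = quadrant_of(delta[i], rec.log2fc)
            if q is None:
                dropped += 1
                continue
            rows.append(
                {
                    "region_id": rec.region_id,
                    "cpg_pos": int(pos[i]),
                    "chrom": chrom,
                    "delta_meth": float(delta[i]),
                    "delta_access": float(rec.log2fc),
                    "quadrant": q,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "region_id", "cpg_pos", "chrom",
            "delta_meth", "delta_access", "quadrant",
        ],
    )
    out.attrs["n_zero_dropped"] = dropped
    return out


def _ranksum_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p by full enumeration of all C(n1+n2, n1) labelings.

    Uses midranks, so ties are handled exactly; the p-value is the fraction
    of labelings whose rank sum deviates from its mean at least as much as
    observed.
    """
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mean_w) - 1e-9
    count = 0
    total = 0
    for combo in combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        if abs(w - mean_w) >= dev:
            count += 1
        total += 1
    return count / total


def _ranksum_normal(x: np.ndarray, y: np.ndarray) -> float:
    """Tie- and continuity-corrected normal approximation."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    w = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return 1.0
    z = (abs(w - mean_w) - 0.5) / np.sqrt(var_w)
    return float(min(1.0, 2 * norm.sf(max(z, 0.0))))


def expression_shift_test(
    gene_set_fc: Sequence[float], background_fc: Sequence[float],
    force_method: str | None = None,
) -> dict:
    """Two-sided Wilcoxon rank-sum comparing a gene set's fold changes
    against a background distribution.

    Exact enumeration when both samples have <= 10 values, normal
    approximation with tie/continuity correction otherwise.
    """
    x = np.asarray(gene_set_fc, dtype=float)
    y = np.asarray(background_fc, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("both samples need >= 3 values")
    exact = len(x) <= WILCOXON_EXACT_MAX and len(y) <= WILCOXON_EXACT_MAX
    if force_method == "exact":
        exact = True
    elif force_method == "normal":
        exact = False
    p = _ranksum_exact(x, y) if exact else _ranksum_normal(x, y)
    return {
        "pvalue": p,
        "median_set": float(np.median(x)),
        "median_background": float(np.median(y)),
        "n_set": len(x),
        "n_background": len(y),
        "method": "exact" if exact else "normal",
    }


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test by hypergeometric tail summation.

    Sums the probabilities of all tables (with the observed margins) whose
    probability does not exceed the observed table's.  The odds ratio is
    (a*d)/(b*c) with a 0.5 Haldane correction applied to every cell when any
    cell is zero.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    k = np.arange(max(0, col1 - (n_total - row1)), min(row1, col1) + 1)
    pmf = hypergeom.pmf(k, n_total, row1, col1)
    p_obs = hypergeom.pmf(a, n_total, row1, col1)
    p = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return odds, p


def fisher_overlap(
    set_regions: Sequence, feature_regions: Sequence,
    universe_regions: Sequence,
) -> OverlapTable:
    """Enrichment of a region set for a genomic feature within a universe.

    Feature membership means >= 1 bp overlap with any feature region.
    """
    from .genomic import overlap_pairs

    set_ids = {r.id for r in set_regions}
    universe_ids = {r.id for r in universe_regions}
    if not set_ids <= universe_ids:
        raise ValueError("set regions must be a subset of the universe")
    if len(universe_ids) < len(set_ids):
        raise ValueError("universe smaller than set")
    in_feature = {p[0] for p in overlap_pairs(universe_regions, feature_regions)}
    a = len(set_ids & in_feature)
    b = len(set_ids - in_feature)
    c = len((universe_ids - set_ids) & in_feature)
    d = len(universe_ids - set_ids - in_feature)
    odds, p = fisher_exact_2x2(a, b, c, d)
    return OverlapTable(a, b, c, d, odds, p)


def mark_enrichment_at(
    scores_state_a: Sequence[float], scores_state_b: Sequence[float],
) -> dict:
    """Compare histone-mark signal over one region set between two states.

    Scores are normalized coverage values; they are log2(x+1)-transformed
    and compared with Welch's two-tailed t-test (robust to unequal
    variances).
    """
    xa = np.log2(np.asarray(scores_state_a, dtype=float) + 1.0)
    xb = np.log2(np.asarray(scores_state_b, dtype=float) + 1.0)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need >= 2 regions per state")
    t_stat, p = ttest_ind(xa, xb, equal_var=False)
    if np.isnan(t_stat):  # both samples constant
        t_stat, p = (0.0, 1.0) if xa.mean() == xb.mean() else (np.inf, 0.0)
    return {
        "t": float(t_stat),
        "pvalue": float(p),
        "mean_a": float(xa.mean()),
        "mean_b": float(xb.mean()),
        "n": len(xa),
    }


def venn_mark_promoters(
    mark_regions: Sequence, primed_promoters: Sequence,
    induced_promoters: Sequence, universe_promoters: Sequence,
) -> dict:
    """Overlap of marked regions with primed/induced promoter classes.

    Returns marked counts per class plus a Fisher p-value for each class
    against the all-promoter universe.
    """
    from .genomic import overlap_pairs

    marked = {p[0] for p in overlap_pairs(universe_promoters, mark_regions)}
    primed_ids = {r.id for r in primed_promoters}
    induced_ids = {r.id for r in induced_promoters}
    if primed_ids & induced_ids:
        raise ValueError("primed and induced promoter sets must be disjoint")
    universe_ids = {r.id for r in universe_promoters}
    out = {
        "n_marked_primed": len(marked & primed_ids),
        "n_marked_induced": len(marked & induced_ids),
        "n_marked_neither": len(marked - primed_ids - induced_ids),
    }
    for label, ids in (("primed", primed_ids), ("induced", induced_ids)):
        a = len(ids & marked)
        b = len(ids - marked)
        c = len((universe_ids - ids) & marked)
        d = len(universe_ids - ids - marked)
        odds, p = fisher_exact_2x2(a, b, c, d)
        out[f"fisher_p_{label}"] = p
        out[f"odds_ratio_{label}"] = odds
    return out


def methylation_kinetics(
    dmls: pd.DataFrame, divisions: Sequence[str]
) -> pd.DataFrame:
    """Per-division mean and s.d. of methylation for a set of CpGs."""
    rows = []
    for div in divisions:
        col = f"meth_{div}"
        rows.append(
            {
                "division": div,
                "mean": float(dmls[col].mean()),
                "sd": float(dmls[col].std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)
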