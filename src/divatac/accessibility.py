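"""Accessibility quantification, rppm normalization, and DAR calling.

rppm ("reads per peak per million") rescales a raw in-region count by the
sequencing effort that actually reached the accessible genome::

    rppm = reads * 1e6 / (unique_reads * FRiP)

where FRiP is the fraction of unique reads falling inside the region set.
Because ``unique_reads * FRiP`` equals the in-region read total, per-sample
rppm sums to exactly one million whenever FRiP was computed from the same
regions being quantified.

Differential accessibility between a division and the undivided (Div0)
reference is assessed with a conditional negative-binomial exact test on
size-factor-scaled group sums, with a single method-of-moments common
dispersion shared across regions, followed by Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-4
LOG2FC_PSEUDOCOUNT = 1.0  # in rppm units


@dataclass(frozen=True)
class SampleStats:
    """Per-sample library statistics entering the rppm formula."""

    sample_id: str
    division: str
    replicate: int
    unique_reads: int
    in_peak_reads: int

    def __post_init__(self) -> None:
        if self.unique_reads <= 0:
            raise ValueError(f"{self.sample_id}: unique_reads must be > 0")
        if not 0 < self.frip <= 1:
            raise ValueError(
                f"{self.sample_id}: FRiP {self.frip} outside (0, 1]"
            )

    @property
    def frip(self) -> float:
        return self.in_peak_reads / self.unique_reads


def count_insertions(cut_sites: np.ndarray, regions: Sequence) -> np.ndarray:
    """Count single-base cut sites per region (half-open containment).

    A site inside several overlapping regions counts once in each.
    """
    sites = np.sort(np.asarray(cut_sites, dtype=np.int64))
    counts = np.empty(len(regions), dtype=np.int64)
    for i, r in enumerate(regions):
        counts[i] = np.searchsorted(sites, r.end) - np.searchsorted(sites, r.start)
    return counts


def rppm_normalize(
    counts: pd.DataFrame,
    unique_reads: Mapping[str, int] | pd.Series,
    frip: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Apply the rppm formula column-wise (samples in columns)."""
    unique_reads = pd.Series(unique_reads)
    frip = pd.Series(frip)
    for s in counts.columns:
        if unique_reads[s] <= 0:
            raise ValueError(f"{s}: unique_reads must be > 0")
        if not 0 < frip[s] <= 1:
            raise ValueError(f"{s}: FRiP {frip[s]} outside (0, 1]")
    scale = 1e6 / (unique_reads[counts.columns] * frip[counts.columns])
    return counts * scale


class AccessibilityMatrix:
    """Region x sample counts plus library stats and the derived rppm."""

    def __init__(self, counts: pd.DataFrame, samples: Sequence[SampleStats]):
        ids = [s.sample_id for s in samples]
        if set(ids) != set(counts.columns):
            raise ValueError("sample sheet does not match count matrix columns")
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        self.counts = counts[ids]
        self.samples = list(samples)
        self._by_id = {s.sample_id: s for s in samples}
        self.rppm = rppm_normalize(
            self.counts,
            {s.sample_id: s.unique_reads for s in samples},
            {s.sample_id: s.frip for s in samples},
        )

    def sample_ids(self, division: str | None = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if division is None or s.division == division
        ]

    def division_mean_rppm(self, division: str) -> pd.Series:
        """Mean rppm over the division's replicates, per region."""
        cols = self.sample_ids(division)
        if not cols:
            raise ValueError(f"no samples for division {division!r}")
        return self.rppm[cols].mean(axis=1)

    @property
    def divisions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.division not in seen:
                seen.append(s.division)
        return seen


def size_factors(counts: np.ndarray, min_positive: int = 50) -> np.ndarray:
    """Median-of-ratios size factors (columns are samples).

    Falls back to total-count ratios when fewer than ``min_positive`` regions
    have all-positive counts.
    """
    counts = np.asarray(counts, dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if all_pos.sum() >= min_positive:
        sub = counts[all_pos]
        ref = np.exp(np.log(sub).mean(axis=1))
        sf = np.median(sub / ref[:, None], axis=0)
    else:
        totals = counts.sum(axis=0)
        sf = totals / np.exp(np.log(np.maximum(totals, 1.0)).mean())
    return sf / np.exp(np.log(sf).mean())  # geometric mean 1


def estimate_common_dispersion(
    scaled: np.ndarray, group: np.ndarray
) -> float:
    """Method-of-moments common NB dispersion across all regions.

    Uses pooled within-group variances so planted group differences do not
    inflate the estimate; the per-region estimates are combined by median and
    floored at ``DISPERSION_FLOOR``.
    """
    group = np.asarray(group)
    means = []
    vars_ = []
    dofs = 0
    pooled_num = np.zeros(scaled.shape[0])
    for g in np.unique(group):
        cols = scaled[:, group == g]
        n = cols.shape[1]
        if n >= 2:
            pooled_num += (n - 1) * cols.var(axis=1, ddof=1)
            dofs += n - 1
    if dofs == 0:
        raise ValueError("need >= 2 replicates in at least one group")
    v = pooled_num / dofs
    m = scaled.mean(axis=1)
    ok = m > 1.0
    if not ok.any():
        return DISPERSION_FLOOR
    alpha = np.median((v[ok] - m[ok]) / m[ok] ** 2)
    return float(max(alpha, DISPERSION_FLOOR))


def nb_exact_test(
    sum_a: int, sum_b: int, n_a: int, n_b: int, alpha: float
) -> float:
    """Two-sided conditional NB exact test on two group sums.

    Each group sum of ``n`` replicates with per-replicate mean ``mu`` and
    dispersion ``alpha`` is NB with mean ``n * mu`` and dispersion
    ``alpha / n``.  Conditioning on the combined total, the p-value sums the
    probabilities of all splits no more likely than the observed one
    (small-probability method), analogous to Fisher's exact test.
    """
    t = int(sum_a) + int(sum_b)
    if t == 0:
        raise ValueError("both groups have zero total counts")
    mu = t / (n_a + n_b)
    k = np.arange(t + 1)
    # size r = n/alpha; success prob r/(r+n*mu) = 1/(1+alpha*mu) for both.
    p_shared = 1.0 / (1.0 + alpha * mu)
    log_fa = nbinom.logpmf(k, n_a / alpha, p_shared)
    log_fb = nbinom.logpmf(k, n_b / alpha, p_shared)
    joint = log_fa + log_fb[::-1]
    log_obs = joint[int(sum_a)]
    total = logsumexp(joint)
    keep = joint <= log_obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(joint[keep]) - total)))


def call_dars(
    matrix: AccessibilityMatrix,
    division: str,
    reference: str = "Div0",
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Call differential accessible regions for a division versus Div0.

    Returns one row per tested region with log2fc (on mean rppm with a
    1-rppm pseudocount), p-value, BH FDR, direction, and the ``is_dar``
    decision (FDR <= fdr_max and |log2fc| >= lfc_min).  Regions with zero
    counts in both groups combined are skipped.
    """
    cols_ref = matrix.sample_ids(reference)
    cols_div = matrix.sample_ids(division)
    if len(cols_ref) < 2 or len(cols_div) < 2:
        raise ValueError("need >= 2 replicates per group")
    cols = cols_ref + cols_div
    raw = matrix.counts[cols].to_numpy(dtype=float)
    sf = size_factors(raw)
    scaled = raw / sf
    group = np.array([0] * len(cols_ref) + [1] * len(cols_div))
    alpha = estimate_common_dispersion(scaled, group)

    sums_ref = np.rint(scaled[:, group == 0].sum(axis=1)).astype(int)
    sums_div = np.rint(scaled[:, group == 1].sum(axis=1)).astype(int)
    mean_ref = matrix.division_mean_rppm(reference).to_numpy()
    mean_div = matrix.division_mean_rppm(division).to_numpy()
    log2fc = np.log2(
        (mean_div + LOG2FC_PSEUDOCOUNT) / (mean_ref + LOG2FC_PSEUDOCOUNT)
    )

    tested = (sums_ref + sums_div) > 0
    pvals = np.ones(tested.sum())
    idx = np.flatnonzero(tested)
    for j, i in enumerate(idx):
        pvals[j] = nb_exact_test(
            sums_ref[i], sums_div[i], len(cols_ref), len(cols_div), alpha
        )
    fdr = multipletests(pvals, method="fdr_bh")[1]

    region_ids = np.asarray(matrix.counts.index)
    out = pd.DataFrame(
        {
            "region_id": region_ids[idx],
            "division": division,
            "log2fc": log2fc[idx],
            "pvalue": pvals,
            "fdr": fdr,
            "direction": np.where(log2fc[idx] >= 0, "up", "down"),
        }
    )
    out["is_dar"] = (out["fdr"] <= fdr_max) & (out["log2fc"].abs() >= lfc_min)
    return out


def division_specific(dar_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Per-division exclusive DAR sets and summary fractions.

    ``exclusive(d)`` removes every region also called in any other division;
    the fraction is reported raw and rounded to integer percent.
    """
    rows = []
    for div, ids in dar_sets.items():
        others: set[str] = set()
        for d2, ids2 in dar_sets.items():
            if d2 != div:
                others |= ids2
        excl = ids - others
        frac = len(excl) / len(ids) if ids else float("nan")
        rows.append(
            {
                "division": div,
                "n_dar": len(ids),
                "n_exclusive": len(excl),
                "fraction_exclusive": frac,
                "percent_exclusive": int(round(100 * frac)) if ids else None,
            }
        )
    return pd.DataFrame(rows)


def read_sample_sheet(path) -> list[SampleStats]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleStats(
            str(r.sample_id),
            str(r.division),
            int(r.replicate),
            int(r.unique_reads),
            int(r.in_peak_reads),
        )
        for r in df.itertuples()
    ]


def write_sample_sheet(samples: Sequence[SampleStats], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "division": [s.division for s in samples],
            "replicate": [s.replicate for s in samples],
            "unique_reads": [s.unique_reads for s in samples],
            "in_peak_reads": [s.in_peak_reads for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)
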