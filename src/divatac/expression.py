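"""Expression filtering, differential expression, and promoter classes.

A gene upregulated between Div8+ and Div0 is classified by its promoter's
accessibility in undivided (Div0) B cells: "induced" promoters start closed
(log2 rppm < 3) and open alongside expression, while "primed" promoters are
already highly accessible (log2 rppm > 5) divisions before the gene is
expressed.  The gap zone [3, 5] and genes that are not upregulated fall in
"other".
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress, ttest_ind
from statsmodels.stats.multitest import multipletests

from .accessibility import (
    LOG2FC_PSEUDOCOUNT,
    estimate_common_dispersion,
    nb_exact_test,
    size_factors,
)

INDUCED_MAX_LOG2RPPM = 3.0
PRIMED_MIN_LOG2RPPM = 5.0
CPM_MIN = 3.0
CPM_MIN_SAMPLES = 3


def filter_expressed(
    counts: pd.DataFrame,
    min_cpm: float = CPM_MIN,
    min_samples: int = CPM_MIN_SAMPLES,
) -> pd.Index:
    """Genes with counts-per-million >= min_cpm in >= min_samples samples.

    The boundary is inclusive: a gene sitting exactly at the cpm floor in
    enough samples is retained.
    """
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    cpm = counts * 1e6 / lib
    return counts.index[(cpm >= min_cpm).sum(axis=1) >= min_samples]


def call_deg(
    counts: pd.DataFrame,
    group_a_cols: Sequence[str],
    group_b_cols: Sequence[str],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Two-group NB exact test on gene counts (B versus A).

    Same machinery as DAR calling: median-of-ratios size factors, a common
    method-of-moments dispersion, conditional exact test on scaled group
    sums, BH correction.  log2fc is computed on mean cpm with a pseudocount.
    Genes with zero counts in both groups combined are skipped.
    """
    if len(group_a_cols) < 2 or len(group_b_cols) < 2:
        raise ValueError("need >= 2 replicates per group")
    cols = list(group_a_cols) + list(group_b_cols)
    raw = counts[cols].to_numpy(dtype=float)
    sf = size_factors(raw)
    scaled = raw / sf
    group = np.array([0] * len(group_a_cols) + [1] * len(group_b_cols))
    alpha = estimate_common_dispersion(scaled, group)

    lib = counts[cols].sum(axis=0)
    cpm = counts[cols] * 1e6 / lib
    mean_a = cpm[list(group_a_cols)].mean(axis=1).to_numpy()
    mean_b = cpm[list(group_b_cols)].mean(axis=1).to_numpy()
    log2fc = np.log2(
        (mean_b + LOG2FC_PSEUDOCOUNT) / (mean_a + LOG2FC_PSEUDOCOUNT)
    )

    sums_a = np.rint(scaled[:, group == 0].sum(axis=1)).astype(int)
    sums_b = np.rint(scaled[:, group == 1].sum(axis=1)).astype(int)
    idx = np.flatnonzero((sums_a + sums_b) > 0)
    pvals = np.empty(len(idx))
    for j, i in enumerate(idx):
        pvals[j] = nb_exact_test(
            sums_a[i], sums_b[i], len(group_a_cols), len(group_b_cols), alpha
        )
    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene_id": np.asarray(counts.index)[idx],
            "log2fc": log2fc[idx],
            "pvalue": pvals,
            "fdr": fdr,
        }
    )
    out["significant"] = out["fdr"] < fdr_max
    return out


def map_gene_promoters(
    annotations: Sequence, div0_rppm: pd.Series
) -> pd.Series:
    """Gene -> promoter region id; strongest Div0 accessibility wins ties."""
    best: dict[str, tuple[float, str]] = {}
    for a in annotations:
        if a.location_class != "promoter" or a.gene_id is None:
            continue
        acc = float(div0_rppm.get(a.region_id, 0.0))
        cur = best.get(a.gene_id)
        if cur is None or acc > cur[0] or (acc == cur[0] and a.region_id < cur[1]):
            best[a.gene_id] = (acc, a.region_id)
    return pd.Series({g: rid for g, (_, rid) in best.items()}, dtype=object)


def classify_primed_induced(
    deg: pd.DataFrame,
    gene_promoter: Mapping[str, str] | pd.Series,
    div0_rppm: pd.Series,
    induced_max: float = INDUCED_MAX_LOG2RPPM,
    primed_min: float = PRIMED_MIN_LOG2RPPM,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Label upregulated genes primed/induced from Div0 promoter rppm.

    Upregulated means significant (BH FDR below the DEG threshold) with
    log2fc > 0 for Div8+ versus Div0.  Genes without a promoter region are
    "other".
    """
    gene_promoter = pd.Series(gene_promoter, dtype=object)
    rows = []
    for rec in deg.itertuples():
        up = bool(rec.significant and rec.log2fc > 0)
        rid = gene_promoter.get(rec.gene_id)
        if rid is None or rid not in div0_rppm.index:
            log2rppm = float("nan")
            cls = "other"
        else:
            log2rppm = float(np.log2(div0_rppm[rid] + pseudocount))
            if not up:
                cls = "other"
            elif log2rppm > primed_min:
                cls = "primed"
            elif log2rppm < induced_max:
                cls = "induced"
            else:
                cls = "other"
        rows.append(
            {
                "gene_id": rec.gene_id,
                "gene_class": cls,
                "div0_promoter_log2rppm": log2rppm,
                "div8_log2fc": rec.log2fc,
                "fdr": rec.fdr,
            }
        )
    return pd.DataFrame(rows)


def kinetics_summary(
    gene_ids: Sequence[str],
    promoter_rppm: pd.DataFrame,
    expression: pd.DataFrame,
    gene_promoter: Mapping[str, str] | pd.Series,
    div_ref: str = "Div0",
    div_late: str = "Div8",
) -> dict:
    """Per-division accessibility/expression distributions for a gene class.

    ``promoter_rppm`` and ``expression`` are regions/genes x divisions.
    Returns quartile summaries per division and Welch t-tests comparing the
    first and last divisions for both modalities.
    """
    gene_ids = [g for g in gene_ids if g in expression.index]
    if not gene_ids:
        raise ValueError("empty gene class")
    gene_promoter = pd.Series(gene_promoter, dtype=object)
    region_ids = [
        gene_promoter[g]
        for g in gene_ids
        if g in gene_promoter.index and gene_promoter[g] in promoter_rppm.index
    ]
    acc = promoter_rppm.loc[region_ids]
    expr = expression.loc[gene_ids]

    def summarize(df: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "division": df.columns,
                "median": df.median(axis=0).to_numpy(),
                "q1": df.quantile(0.25, axis=0).to_numpy(),
                "q3": df.quantile(0.75, axis=0).to_numpy(),
            }
        )

    t_acc = ttest_ind(acc[div_ref], acc[div_late], equal_var=False)
    t_expr = ttest_ind(expr[div_ref], expr[div_late], equal_var=False)
    return {
        "accessibility": summarize(acc),
        "expression": summarize(expr),
        "accessibility_t": float(t_acc.statistic),
        "accessibility_p": float(t_acc.pvalue),
        "expression_t": float(t_expr.statistic),
        "expression_p": float(t_expr.pvalue),
        "n_genes": len(gene_ids),
    }


def access_expression_regression(
    delta_access: Sequence[float],
    delta_expr: Sequence[float],
    location_class: Sequence[str] | None = None,
) -> dict:
    """OLS of expression change on accessibility change.

    When ``location_class`` is given, fits are computed separately per
    class (promoter / distal); otherwise a single fit is returned under the
    key "all".  Each fit needs >= 3 points with non-constant x.
    """
    x = np.asarray(delta_access, dtype=float)
    y = np.asarray(delta_expr, dtype=float)
    if location_class is None:
        groups = {"all": np.ones(len(x), dtype=bool)}
    else:
        lc = np.asarray(location_class)
        groups = {c: lc == c for c in ("promoter", "distal") if (lc == c).any()}
    out = {}
    for name, mask in groups.items():
        xs, ys = x[mask], y[mask]
        if len(xs) < 3:
            raise ValueError(f"{name}: need >= 3 paired points")
        if np.ptp(xs) == 0:
            raise ValueError(f"{name}: accessibility changes are constant")
        fit = linregress(xs, ys)
        out[name] = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r": float(fit.rvalue),
            "pvalue": float(fit.pvalue),
            "n": int(len(xs)),
        }
    return out
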