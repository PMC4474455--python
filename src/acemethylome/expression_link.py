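"""Promoter methylation versus expression change between WT and TKO.

Genes pass a three-step filter (both FPKM values positive, FPKM sum above
1, log2 fold change within [−6, 6]); fold change is log2(TKO/WT), so a
positive value means induction upon complete loss of DNA methylation.
Genes beyond ±2.5 are classified up-/down-regulated.  For the subgroup
analysis, filtered genes are sorted by fold change (or WT FPKM) and cut
into equal-count subgroups; each subgroup reports its median fold change,
the pooled methylation of all CG sites within 500 bp of its members'
TSSs, the CG count, and median FPKM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "add_fold_change",
    "filter_genes",
    "classify_deregulated",
    "promoter_methylation",
    "subgroup_analysis",
]


def add_fold_change(table: pd.DataFrame, direction: str = "tko_over_wt") -> pd.DataFrame:
    """Attach ``log2_fc`` to an FPKM table (positive = higher in TKO)."""
    out = table.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (
            out["fpkm_tko"] / out["fpkm_wt"]
            if direction == "tko_over_wt"
            else out["fpkm_wt"] / out["fpkm_tko"]
        )
        out["log2_fc"] = np.log2(ratio)
    return out


def filter_genes(
    table: pd.DataFrame, fc_range: tuple[float, float] = (-6.0, 6.0)
) -> tuple[pd.DataFrame, dict]:
    """Filter cascade: FPKM>0 in both, FPKM sum>1, fold change in range.

    Returns the retained rows (with ``log2_fc`` attached) and the number
    of genes removed by each criterion, applied in order.
    """
    t = add_fold_change(table)
    counts = {}
    ok1 = (t.fpkm_wt > 0) & (t.fpkm_tko > 0)
    counts["fpkm_positive"] = int((~ok1).sum())
    t = t[ok1]
    ok2 = (t.fpkm_wt + t.fpkm_tko) > 1
    counts["fpkm_sum"] = int((~ok2).sum())
    t = t[ok2]
    ok3 = (t.log2_fc >= fc_range[0]) & (t.log2_fc <= fc_range[1])
    counts["fc_range"] = int((~ok3).sum())
    return t[ok3].reset_index(drop=True), counts


def classify_deregulated(log2_fc, threshold: float = 2.5):
    """'up' above the threshold, 'down' below its negative, else 'unchanged'.

    Both cuts are strict, so a gene exactly at the threshold is unchanged.
    """
    fc = np.asarray(log2_fc, dtype=float)
    out = np.where(fc > threshold, "up",
                   np.where(fc < -threshold, "down", "unchanged"))
    return str(out) if out.ndim == 0 else out


def promoter_methylation(
    genes: pd.DataFrame,
    sites: pd.DataFrame,
    half_window: int = 500,
    density_window: int = 300,
) -> pd.DataFrame:
    """Per-gene promoter counts from a combined-strand CG site table.

    For each gene the CG sites within TSS ± ``half_window`` contribute
    their raw counts (``prom_rC``/``prom_rT``) and count (``prom_cg``);
    ``prom_density`` is the CG count within TSS ± ``density_window`` —
    the 600-bp-window density at the TSS.
    """
    by_chrom = {}
    for chrom, sub in sites.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        by_chrom[chrom] = (
            sub.pos.to_numpy(),
            (sub.rC_p + sub.rC_n).to_numpy(),
            (sub.rT_p + sub.rT_n).to_numpy(),
        )
    rows = []
    for _, g in genes.iterrows():
        tss = int(g["start"]) if g["strand"] == "+" else int(g["end"]) - 1
        pos, r_c, r_t = by_chrom.get(
            g["chrom"], (np.empty(0, dtype=int), np.empty(0), np.empty(0))
        )
        i, j = np.searchsorted(pos, [tss - half_window, tss + half_window + 1])
        di, dj = np.searchsorted(pos, [tss - density_window,
                                       tss + density_window + 1])
        rows.append((g["name"], int(r_c[i:j].sum()), int(r_t[i:j].sum()),
                     int(j - i), int(dj - di)))
    return pd.DataFrame(
        rows, columns=["gene", "prom_rC", "prom_rT", "prom_cg", "prom_density"]
    )


def subgroup_analysis(
    genes: pd.DataFrame,
    n_groups: int = 500,
    sort_by: str = "fc",
) -> pd.DataFrame:
    """Equal-count subgroup summary of filtered genes.

    ``genes`` must carry ``log2_fc``, ``fpkm_wt``, and promoter columns
    from :func:`promoter_methylation`.  Genes are sorted by the chosen key
    (``'fc'`` or ``'fpkm'``) and partitioned into ``n_groups`` equal-count
    groups, remainders going to the earliest groups.  Each subgroup
    reports median fold change, pooled promoter MR, total promoter CG
    count, median promoter CG density, and median WT FPKM.
    """
    if len(genes) < n_groups:
        raise ValueError(
            f"only {len(genes)} genes for {n_groups} groups; "
            "reduce n_groups"
        )
    key = {"fc": "log2_fc", "fpkm": "fpkm_wt"}[sort_by]
    ordered = genes.sort_values(key, kind="mergesort", ignore_index=True)
    parts = np.array_split(np.arange(len(ordered)), n_groups)
    rows = []
    for gi, members in enumerate(parts, start=1):
        sub = ordered.iloc[members]
        r_c, r_t = sub.prom_rC.sum(), sub.prom_rT.sum()
        rows.append((
            gi,
            len(sub),
            float(sub.log2_fc.median()),
            float(r_c / (r_c + r_t)) if (r_c + r_t) else float("nan"),
            int(sub.prom_cg.sum()),
            float(sub.prom_density.median()),
            float(sub.fpkm_wt.median()),
        ))
    return pd.DataFrame(
        rows, columns=["group", "n_genes", "median_fc", "mr", "cg_count",
                       "median_density", "median_fpkm"]
    )
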