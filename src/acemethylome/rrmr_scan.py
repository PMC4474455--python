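"""Reduction-resistant methylated region (RRMR) discovery.

The deletion index Di = (Swt − Sko) / Swt measures the fractional loss of
methylation at a CG site in a DNMT knockout relative to wild type (Di is
undefined when the site is unmethylated in WT).  An RRMR is a maximal run
of consecutive CG sites — consecutive among sites covered in both genotypes
above the coverage floor, so uncovered sites are transparent rather than
run-breakers — in which every site has Di strictly below the threshold.
Defaults follow the knockout being scanned: runs of at least 7 sites for
the DNMT3a/3b double knockout, 5 for the DNMT1 single knockout, Di < 0.3.

Discovered regions are assigned to nearby RepeatMasker-style repeat
annotations within a gap tolerance and tested for class/family/subtype
enrichment with Fisher's exact test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "deletion_index",
    "find_rrmrs",
    "overlap_repeats",
    "enrichment_test",
    "enrich_by_level",
    "ltr_subtype_table",
    "METHYLATION_RANGES",
]


def deletion_index(swt, sko):
    """Di = (Swt − Sko) / Swt; NaN when Swt = 0 (no WT methylation to lose)."""
    swt = np.asarray(swt, dtype=float)
    sko = np.asarray(sko, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        di = np.where(swt > 0, (swt - sko) / np.where(swt > 0, swt, 1), np.nan)
    return float(di) if di.ndim == 0 else di


def find_rrmrs(
    wt_sites: pd.DataFrame,
    ko_sites: pd.DataFrame,
    min_run: int = 7,
    di_threshold: float = 0.3,
    min_coverage: int = 7,
) -> pd.DataFrame:
    """Maximal runs of consecutive reduction-resistant CG sites.

    ``wt_sites``/``ko_sites`` are combined-strand CG tables (columns
    ``chrom, pos, S_combined, coverage, rC_*, rT_*``).  Sites participate
    only if covered at least ``min_coverage`` in both genotypes;
    consecutiveness is evaluated among participating sites.  A site
    qualifies when its Di is defined and strictly below ``di_threshold``.
    Each output region spans the first to last CG of the run (end =
    last C + 2) and carries per-genotype pooled methylation.
    """
    cols = ["chrom", "pos", "S_combined", "coverage", "rC_p", "rC_n",
            "rT_p", "rT_n"]
    wt = wt_sites[cols].rename(columns={"S_combined": "Swt"})
    ko = ko_sites[cols].rename(columns={"S_combined": "Sko"})
    merged = wt.merge(ko, on=["chrom", "pos"], suffixes=("_wt", "_ko"))
    merged = merged[
        (merged.coverage_wt >= min_coverage) & (merged.coverage_ko >= min_coverage)
    ].sort_values(["chrom", "pos"], ignore_index=True)
    merged["Di"] = deletion_index(merged.Swt.to_numpy(), merged.Sko.to_numpy())

    rows = []
    for chrom, sub in merged.groupby("chrom", sort=True):
        ok = (sub.Di < di_threshold).fillna(False).to_numpy()
        pos = sub.pos.to_numpy()
        i = 0
        n = ok.size
        while i < n:
            if not ok[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                run = sub.iloc[i:j + 1]
                mr_wt = (run.rC_p_wt + run.rC_n_wt).sum() / max(
                    1, (run.rC_p_wt + run.rC_n_wt + run.rT_p_wt + run.rT_n_wt).sum()
                )
                mr_ko = (run.rC_p_ko + run.rC_n_ko).sum() / max(
                    1, (run.rC_p_ko + run.rC_n_ko + run.rT_p_ko + run.rT_n_ko).sum()
                )
                rows.append((chrom, int(pos[i]), int(pos[j]) + 2, j - i + 1,
                             float(mr_wt), float(mr_ko)))
            i = j + 1
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_cg", "mr_wt", "mr_ko"]
    )


def _interval_distance(a_start, a_end, b_start, b_end):
    """Gap between two half-open intervals; overlap counts as distance 0."""
    return max(0, max(b_start - a_end, a_start - b_end))


def _interval_overlap(a_start, a_end, b_start, b_end):
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def overlap_repeats(
    rrmrs: pd.DataFrame, repeats: pd.DataFrame, gap: int = 50
) -> pd.DataFrame:
    """Assign each RRMR to the nearest repeat within ``gap`` bases.

    Ties on distance go to the larger overlap, then to the repeat first in
    coordinate order.  Unassigned regions keep NaN annotation columns.
    """
    reps = repeats.sort_values(["chrom", "start"], ignore_index=True)
    out_rows = []
    for r in rrmrs.itertuples(index=False):
        sub = reps[reps.chrom == r.chrom]
        best = None
        for _, rep in sub.iterrows():
            d = _interval_distance(r.start, r.end, rep["start"], rep["end"])
            if d > gap:
                continue
            ov = _interval_overlap(r.start, r.end, rep["start"], rep["end"])
            key = (d, -ov, rep["start"])
            if best is None or key < best[0]:
                best = (key, rep)
        if best is None:
            out_rows.append((r.chrom, r.start, r.end, r.n_cg, False,
                             np.nan, np.nan, np.nan, np.nan, np.nan))
        else:
            rep = best[1]
            out_rows.append((
                r.chrom, r.start, r.end, r.n_cg, True, rep["name"],
                rep["family"], rep["class"], best[0][0], -best[0][1],
            ))
    out = pd.DataFrame(
        out_rows,
        columns=["chrom", "start", "end", "n_cg", "assigned", "subtype",
                 "family", "class", "distance", "overlap"],
    )
    return out


def enrichment_test(a: int, b: int, c: int, d: int):
    """Fisher's exact test on the 2×2 table [[a, b], [c, d]].

    Rows: RRMRs in / not in the class of interest; background composition
    in / not in the class.  Returns ``(odds_ratio, p_two_sided)``; a zero
    margin yields p = 1 with a warning.
    """
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("contingency table has a zero margin; p set to 1")
        return float("nan"), 1.0
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def enrich_by_level(
    assignment: pd.DataFrame, repeats: pd.DataFrame, level: str = "class"
) -> pd.DataFrame:
    """Per-class (or family/subtype) enrichment of assigned RRMRs.

    The baseline is the count composition of the repeat annotation:
    for each label, the 2×2 table compares assigned-RRMR counts in/out of
    the label against repeat-element counts in/out of the label.
    """
    col = {"class": "class", "family": "family", "subtype": "name"}[level]
    assigned = assignment[assignment.assigned]
    a_col = {"class": "class", "family": "family", "subtype": "subtype"}[level]
    total_r = len(assigned)
    total_g = len(repeats)
    rows = []
    for label in sorted(repeats[col].dropna().unique()):
        a = int((assigned[a_col] == label).sum())
        g = int((repeats[col] == label).sum())
        odds, p = enrichment_test(a, total_r - a, g, total_g - g)
        rows.append((label, a, total_r, g, total_g, odds, p))
    return pd.DataFrame(
        rows, columns=[level, "rrmrs_in", "rrmrs_total", "genome_in",
                       "genome_total", "odds_ratio", "p_value"]
    )


# six methylation-level ranges; all half-open except the final one, which is
# closed at 1 so a fully methylated element still falls in the top range
METHYLATION_RANGES = [(0.0, 0.1), (0.1, 0.2), (0.2, 0.3), (0.3, 0.4),
                      (0.4, 0.5), (0.5, 1.0)]


def ltr_subtype_table(
    elements: pd.DataFrame, min_members: int = 50
) -> pd.DataFrame:
    """Fraction of each LTR subtype's members per methylation range.

    ``elements`` needs ``subtype`` and ``mr`` columns (element-level pooled
    methylation, already filtered).  Subtypes with ``min_members`` or fewer
    members are excluded.  Rows are ordered by the fraction in the highest
    range [0.5, 1], then the next highest, descending.
    """
    edges = np.array([lo for lo, _ in METHYLATION_RANGES] + [1.0])
    labels = [f"[{lo},{hi}]" for lo, hi in METHYLATION_RANGES]
    rows = []
    for subtype, sub in elements.groupby("subtype"):
        if len(sub) <= min_members:
            continue
        mr = sub.mr.to_numpy(dtype=float)
        idx = np.clip(np.digitize(mr, edges[1:], right=False), 0,
                      len(labels) - 1)
        fracs = np.bincount(idx, minlength=len(labels)) / mr.size
        rows.append([subtype, len(sub)] + fracs.tolist())
    out = pd.DataFrame(rows, columns=["subtype", "n_members"] + labels)
    if not out.empty:
        out = out.sort_values(
            [labels[-1], labels[-2]], ascending=False, ignore_index=True
        )
    return out
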