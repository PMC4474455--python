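"""Element-level methylation profiling for genes, LINEs, and LTRs.

Implements the element filter cascade (length, CG count, summed coverage in
every genotype under comparison), the LINE promoter definitions (a fixed
window 100 bp upstream to 1000 bp downstream of the TSS, or the downstream
quarter of the element), equal-CG binning of element bodies, grouping by CG
density deciles or coverage tertiles, and the equal-length promoter
methylation matrix around gene TSSs.

Site tables used here are combined-strand CG tables keyed by the
plus-strand C position; pooled (count-weighted) methylation is used for
every aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import cg_start_positions

__all__ = [
    "ElementFilter",
    "LINE_FILTER",
    "LTR_FILTER",
    "BODY_FILTERS",
    "line_promoter",
    "filter_elements",
    "element_mr",
    "bin_equal_cg",
    "profile_groups",
    "gene_promoter_profile",
]


@dataclass
class ElementFilter:
    kind: str
    min_length: int = 0
    min_cg: int = 0
    min_coverage: int = 0
    region_rule: str = "full"  # full | LINE_promoter | gene_promoter


# element-selection defaults for the promoter/full-element analyses
LINE_FILTER = ElementFilter("LINE", min_length=1500, min_cg=30,
                            min_coverage=50, region_rule="LINE_promoter")
LTR_FILTER = ElementFilter("LTR", min_cg=9, min_coverage=50)
# body-profile defaults (equal-CG binning): genes 50 bins, LINEs 20, LTRs 15
BODY_FILTERS = {
    "gene": (ElementFilter("gene", min_length=3000, min_cg=50), 50),
    "LINE": (ElementFilter("LINE", min_length=1000, min_cg=20), 20),
    "LTR": (ElementFilter("LTR", min_length=300, min_cg=15), 15),
}


def line_promoter(
    start: int,
    end: int,
    strand: str,
    rule: str = "fixed",
    chrom_length: int | None = None,
) -> tuple[int, int]:
    """Promoter interval of a LINE.

    ``rule='fixed'``: 100 bp upstream to 1000 bp downstream of the TSS,
    strand-aware, clipped to the chromosome.  ``rule='quarter'``: the
    downstream quarter of the element itself (used for repeat overlap).
    """
    if rule == "fixed":
        if strand == "+":
            ps, pe = start - 100, start + 1000
        else:
            ps, pe = end - 1000, end + 100
        ps = max(0, ps)
        if chrom_length is not None:
            pe = min(pe, chrom_length)
        return ps, pe
    if rule == "quarter":
        quarter = (end - start) // 4
        return (start, start + quarter) if strand == "+" else (end - quarter, end)
    raise ValueError(f"unknown promoter rule {rule!r}")


def _sites_in(sites_by_chrom, chrom, lo, hi):
    """Rows of a per-chromosome site table with lo <= pos < hi."""
    if chrom not in sites_by_chrom:
        return None
    pos, df = sites_by_chrom[chrom]
    i, j = np.searchsorted(pos, [lo, hi])
    return df.iloc[i:j]


def _index_sites(sites: pd.DataFrame):
    out = {}
    for chrom, sub in sites.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        out[chrom] = (sub.pos.to_numpy(), sub.reset_index(drop=True))
    return out


def element_mr(sub: pd.DataFrame) -> float:
    """Pooled MR of a site-table slice (NaN without coverage)."""
    if sub is None or sub.empty:
        return float("nan")
    r_c = (sub.rC_p + sub.rC_n).sum()
    r_t = (sub.rT_p + sub.rT_n).sum()
    return float(r_c / (r_c + r_t)) if (r_c + r_t) > 0 else float("nan")


def filter_elements(
    elements: pd.DataFrame,
    genome,
    site_tables: dict[str, pd.DataFrame],
    filt: ElementFilter,
) -> pd.DataFrame:
    """Apply the length / CG-count / coverage cascade to an element table.

    ``site_tables`` maps genotype name to its combined-strand CG table; an
    element is retained only when its summed site coverage exceeds
    ``min_coverage`` in *every* genotype.  Length and CG count are strict
    inequalities evaluated on the full element; the analysis region (e.g.
    LINE promoter) and its pooled MR per genotype are attached as columns.
    """
    sequences = genome.sequences if hasattr(genome, "sequences") else genome
    cg_by_chrom = {c: cg_start_positions(s.upper()) for c, s in sequences.items()}
    indexed = {gt: _index_sites(df) for gt, df in site_tables.items()}
    rows = []
    for _, el in elements.iterrows():
        chrom, s, e = el["chrom"], int(el["start"]), int(el["end"])
        length = e - s
        if filt.min_length and length <= filt.min_length:
            continue
        cg = cg_by_chrom.get(chrom)
        n_cg = int(np.searchsorted(cg, e) - np.searchsorted(cg, s)) if cg is not None else 0
        if filt.min_cg and n_cg <= filt.min_cg:
            continue
        if filt.region_rule == "LINE_promoter":
            rs, re = line_promoter(s, e, el["strand"],
                                   chrom_length=len(sequences[chrom]))
        else:
            rs, re = s, e
        covs, mrs = {}, {}
        for gt, idx in indexed.items():
            full = _sites_in(idx, chrom, s, e)
            covs[gt] = int(full.coverage.sum()) if full is not None else 0
            mrs[gt] = element_mr(_sites_in(idx, chrom, rs, re))
        if filt.min_coverage and any(v <= filt.min_coverage for v in covs.values()):
            continue
        row = dict(el)
        row.update({"n_cg": n_cg, "region_start": rs, "region_end": re})
        row.update({f"cov_{gt}": v for gt, v in covs.items()})
        row.update({f"mr_{gt}": v for gt, v in mrs.items()})
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def bin_equal_cg(site_positions, strand: str, n_bins: int) -> list[np.ndarray]:
    """Split an element's CG sites into bins of (near-)equal site count.

    ``site_positions`` are ascending genomic positions within the element.
    Bins are ordered 5'→3' in element orientation; counts differ by at
    most one, with the remainder going to the earliest bins.
    """
    pos = np.asarray(site_positions)
    n = pos.size
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds CG count {n}")
    ordered = pos if strand == "+" else pos[::-1]
    base, rem = divmod(n, n_bins)
    bins, k = [], 0
    for b in range(n_bins):
        size = base + (1 if b < rem else 0)
        bins.append(ordered[k:k + size])
        k += size
    return bins


def profile_groups(
    elements: pd.DataFrame,
    sites: pd.DataFrame,
    group_by: str = "cg_density",
    n_groups: int = 10,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Grouped, binned methylation profile across elements.

    Elements are sorted by the grouping key (element CG count for
    ``'cg_density'``; summed coverage for ``'coverage'``, giving the
    lowest-coverage group first) and partitioned into ``n_groups``
    equal-count groups.  Within a group, bins of the same ordinal are
    pooled across member elements: the cell MR is ΣrC/(ΣrC+ΣrT) and the
    cell density is the median site CG density.  Returns a long-format
    frame (group, bin, n_sites, rC, rT, mr, median_density).
    """
    key = {"cg_density": "n_cg", "coverage": None}[group_by]
    if key is None:
        cov_cols = [c for c in elements.columns if c.startswith("cov_")]
        sort_key = elements[cov_cols].sum(axis=1)
    else:
        sort_key = elements[key]
    order = np.argsort(sort_key.to_numpy(), kind="mergesort")
    groups = np.array_split(order, n_groups)

    indexed = _index_sites(sites)
    acc: dict[tuple, list] = {}
    for gi, members in enumerate(groups, start=1):
        for m in members:
            el = elements.iloc[m]
            sub = _sites_in(indexed, el["chrom"], int(el["start"]), int(el["end"]))
            if sub is None or sub.empty:
                continue
            try:
                bins = bin_equal_cg(sub.pos.to_numpy(), el["strand"], n_bins)
            except ValueError:
                continue
            pos_to_row = dict(zip(sub.pos, range(len(sub))))
            for bi, members_pos in enumerate(bins, start=1):
                rows = sub.iloc[[pos_to_row[p] for p in members_pos]]
                cell = acc.setdefault((gi, bi), [0, 0, 0, []])
                cell[0] += int((rows.rC_p + rows.rC_n).sum())
                cell[1] += int((rows.rT_p + rows.rT_n).sum())
                cell[2] += len(rows)
                if "cg_density" in rows:
                    cell[3].extend(rows.cg_density.tolist())
    out = []
    for (gi, bi), (r_c, r_t, n_sites, dens) in sorted(acc.items()):
        mr = r_c / (r_c + r_t) if (r_c + r_t) else float("nan")
        out.append((gi, bi, n_sites, r_c, r_t, mr,
                    float(np.median(dens)) if dens else float("nan")))
    return pd.DataFrame(
        out, columns=["group", "bin", "n_sites", "rC", "rT", "mr",
                      "median_density"]
    )


def gene_promoter_profile(
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    sites: pd.DataFrame,
    n_groups: int = 500,
    n_bins: int = 40,
    half_window: int = 4000,
) -> tuple[pd.DataFrame, int]:
    """Equal-length binned methylation around gene TSSs, expression-sorted.

    Genes are joined to the expression table (genes without an expression
    value are excluded; their count is returned), sorted by FPKM then
    promoter CG count (descending), and split into ``n_groups`` equal-count
    groups.  The TSS ± ``half_window`` region is divided into ``n_bins``
    equal-length strand-aware bins (bin 1 most upstream) and each
    group × bin cell holds the pooled MR.  Returns ``(matrix, n_excluded)``
    where the matrix is ``n_groups`` rows × ``n_bins`` columns.
    """
    width = (2 * half_window) // n_bins
    merged = genes.merge(expression, left_on="name", right_on="gene",
                         how="left")
    excluded = int(merged["fpkm_wt"].isna().sum())
    merged = merged[merged["fpkm_wt"].notna()].reset_index(drop=True)
    indexed = _index_sites(sites)

    # promoter CG count as the secondary sort key
    cg_counts = []
    for _, g in merged.iterrows():
        tss = int(g["start"]) if g["strand"] == "+" else int(g["end"]) - 1
        sub = _sites_in(indexed, g["chrom"], tss - half_window,
                        tss + half_window)
        cg_counts.append(0 if sub is None else len(sub))
    merged["promoter_cg"] = cg_counts
    merged = merged.sort_values(["fpkm_wt", "promoter_cg"],
                                ascending=False, ignore_index=True)

    groups = np.array_split(np.arange(len(merged)), n_groups)
    r_c = np.zeros((n_groups, n_bins))
    r_t = np.zeros((n_groups, n_bins))
    for gi, members in enumerate(groups):
        for m in members:
            g = merged.iloc[m]
            tss = int(g["start"]) if g["strand"] == "+" else int(g["end"]) - 1
            lo = tss - half_window
            sub = _sites_in(indexed, g["chrom"], lo, tss + half_window)
            if sub is None or sub.empty:
                continue
            b = np.minimum((sub.pos.to_numpy() - lo) // width, n_bins - 1)
            if g["strand"] == "-":
                b = n_bins - 1 - b
            np.add.at(r_c[gi], b, (sub.rC_p + sub.rC_n).to_numpy())
            np.add.at(r_t[gi], b, (sub.rT_p + sub.rT_n).to_numpy())
    with np.errstate(invalid="ignore"):
        mr = np.where(r_c + r_t > 0, r_c / np.maximum(r_c + r_t, 1), np.nan)
    matrix = pd.DataFrame(
        mr, index=[f"g{i + 1}" for i in range(n_groups)],
        columns=[f"bin{j + 1}" for j in range(n_bins)],
    )
    return matrix, excluded
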