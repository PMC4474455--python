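"""Strand-symmetry statistics for CG methylation.

The bias index BI = (Sn − Sp) / (Sn + Sp) measures how asymmetrically one
CG dinucleotide is methylated on its two strands: 0 means symmetric, ±1
means methylation confined to a single strand.  A site with Sn = Sp = 0 is
treated as unbiased (BI = 0) rather than undefined.  Sense/antisense
agreement across many sites is summarized by the Pearson correlation of
(Sp, Sn) over sites with adequate coverage on each strand.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["bias_index", "strand_correlation", "bi_distribution"]


def bias_index(sn, sp):
    """BI = (Sn − Sp) / (Sn + Sp), with the 0/0 case defined as 0."""
    sn = np.asarray(sn, dtype=float)
    sp = np.asarray(sp, dtype=float)
    tot = sn + sp
    with np.errstate(invalid="ignore", divide="ignore"):
        bi = np.where(tot > 0, (sn - sp) / np.where(tot > 0, tot, 1), 0.0)
    return float(bi) if bi.ndim == 0 else bi


def strand_correlation(sites: pd.DataFrame, min_cov_per_strand: int = 10):
    """Pearson correlation of per-strand MRs over well-covered CG sites.

    ``sites`` is a combined-strand CG table with ``Sp``/``Sn`` and
    ``cov_p``/``cov_n`` columns; only sites with at least
    ``min_cov_per_strand`` reads on *each* strand enter.  Returns NaN (with
    a warning) when fewer than two sites pass or the passing sites are
    degenerate (zero variance on either strand).
    """
    ok = (sites["cov_p"] >= min_cov_per_strand) & (
        sites["cov_n"] >= min_cov_per_strand
    )
    sp = sites.loc[ok, "Sp"].to_numpy(dtype=float)
    sn = sites.loc[ok, "Sn"].to_numpy(dtype=float)
    if sp.size < 2:
        warnings.warn("fewer than 2 sites pass the coverage filter")
        return float("nan")
    if np.ptp(sp) == 0 or np.ptp(sn) == 0:
        warnings.warn("zero variance on one strand; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(sp, sn).statistic)


def bi_distribution(
    bi_values,
    range_lo: float = -0.2,
    range_hi: float = 0.2,
    bin_width: float = 0.05,
):
    """Fraction of sites with BI inside [lo, hi] plus a histogram over [−1, 1].

    Returns ``(fraction, (counts, edges))``; the fraction is NaN on empty
    input.
    """
    bi = np.asarray(bi_values, dtype=float)
    bi = bi[~np.isnan(bi)]
    n_bins = int(round(2.0 / bin_width))
    counts, edges = np.histogram(bi, bins=n_bins, range=(-1.0, 1.0))
    if bi.size == 0:
        return float("nan"), (counts, edges)
    frac = float(((bi >= range_lo) & (bi <= range_hi)).mean())
    return frac, (counts, edges)
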