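"""Per-cytosine pileup and methylation-rate statistics.

The methylation rate (MR) at one cytosine is S = rC / (rC + rT), where rC
counts aligned reads retaining C after bisulfite treatment and rT counts
reads converted to T.  Overall methylation of a region pools the raw counts
first (S = ΣrC / (ΣrC + ΣrT)) rather than averaging per-site rates.  Except
for strand-bias analyses, the two cytosines of a CG dinucleotide are
combined into one site record.

Coordinates are 0-based half-open internally; the CX-style export writes
1-based positions to match the common dialect.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._seq import A, C, G, T, cg_start_positions, to_array

__all__ = [
    "classify_context",
    "primary_context",
    "pileup",
    "methylation_rate",
    "overall_methylation",
    "combine_cg_strands",
    "cg_density",
    "write_cx_report",
]

_COMP_CODE = {A: T, C: G, G: C, T: A}


def _base(seq: str, i: int) -> int | None:
    if 0 <= i < len(seq):
        return ord(seq[i])
    return None


def classify_context(genome, chrom: str, pos: int, strand: str) -> frozenset:
    """Sequence context flags of a cytosine, from the reference.

    Returns a frozenset of non-exclusive labels: exactly one of
    ``CG``/``CHG``/``CHH`` (the primary context) plus any of ``CWG`` (the
    triplet C[A/T]G), ``GC`` (preceded by G), and ``GWC`` (G[A/T] before
    the C).  Raises ``ValueError`` when the addressed base is not a
    cytosine on the given strand.
    """
    sequences = genome.sequences if hasattr(genome, "sequences") else genome
    seq = sequences[chrom].upper()
    if strand == "+":
        here = _base(seq, pos)
        nxt1, nxt2 = _base(seq, pos + 1), _base(seq, pos + 2)
        prv1, prv2 = _base(seq, pos - 1), _base(seq, pos - 2)
        expect = C
    elif strand == "-":
        here = _base(seq, pos)
        comp = lambda b: _COMP_CODE.get(b) if b is not None else None
        here = comp(here) if here is not None else None
        nxt1, nxt2 = comp(_base(seq, pos - 1)), comp(_base(seq, pos - 2))
        prv1, prv2 = comp(_base(seq, pos + 1)), comp(_base(seq, pos + 2))
        expect = C
    else:
        raise ValueError("strand must be '+' or '-'")
    if here != expect:
        raise ValueError(f"{chrom}:{pos} ({strand}) is not a cytosine")
    labels = set()
    if nxt1 == G:
        labels.add("CG")
    elif nxt2 == G:
        labels.add("CHG")
        if nxt1 in (A, T):
            labels.add("CWG")
    else:
        labels.add("CHH")
    if prv1 == G:
        labels.add("GC")
    if prv2 == G and prv1 in (A, T):
        labels.add("GWC")
    return frozenset(labels)


def primary_context(labels: frozenset) -> str:
    for name in ("CG", "CHG", "CHH"):
        if name in labels:
            return name
    raise ValueError("no primary context present")


def _context_codes(arr: np.ndarray, positions: np.ndarray, strand: str) -> np.ndarray:
    """Vectorised primary contexts of cytosine positions on one strand."""
    n = arr.size
    if strand == "+":
        nxt1 = np.where(positions + 1 < n, arr[np.minimum(positions + 1, n - 1)], A)
        nxt2 = np.where(positions + 2 < n, arr[np.minimum(positions + 2, n - 1)], A)
        return np.where(nxt1 == G, "CG", np.where(nxt2 == G, "CHG", "CHH"))
    nxt1 = np.where(positions - 1 >= 0, arr[np.maximum(positions - 1, 0)], T)
    nxt2 = np.where(positions - 2 >= 0, arr[np.maximum(positions - 2, 0)], T)
    return np.where(nxt1 == C, "CG", np.where(nxt2 == C, "CHG", "CHH"))


def pileup(clones: pd.DataFrame, genome) -> pd.DataFrame:
    """Count C/T read support at every covered reference cytosine.

    ``clones`` is a (deduplicated) alignment table in the shared schema;
    only the bisulfite strand a fragment derives from is interrogated.
    Read bases other than C or T at a cytosine are excluded from both
    counts.  Where the two mates of a fragment overlap, the overlapped
    positions are counted once (from read 1).  Records extending past the
    chromosome end are skipped with a warning.
    """
    sequences = genome.sequences if hasattr(genome, "sequences") else genome
    arrs = {c: to_array(s.upper()) for c, s in sequences.items()}
    acc: dict[str, dict[str, np.ndarray]] = {
        c: {
            "rC_p": np.zeros(a.size, dtype=np.int64),
            "rT_p": np.zeros(a.size, dtype=np.int64),
            "rC_m": np.zeros(a.size, dtype=np.int64),
            "rT_m": np.zeros(a.size, dtype=np.int64),
        }
        for c, a in arrs.items()
    }

    def _count(chrom, lo, hi, base_at, strand):
        """base_at(p) gives the original-strand read base at reference p."""
        arr = arrs[chrom]
        sub = arr[lo:hi]
        ref = C if strand == "+" else G
        idx = np.nonzero(sub == ref)[0]
        suffix = "p" if strand == "+" else "m"
        for i in idx:
            p = lo + int(i)
            b = base_at(p)
            if b == C:
                acc[chrom][f"rC_{suffix}"][p] += 1
            elif b == T:
                acc[chrom][f"rT_{suffix}"][p] += 1

    for row in clones.itertuples(index=False):
        if row.chrom is None or row.chrom not in arrs:
            continue
        n = arrs[row.chrom].size
        if min(row.start1, row.start2) < 0 or max(row.end1, row.end2) > n:
            warnings.warn(f"alignment beyond bounds of {row.chrom}; skipped")
            continue
        s1 = to_array(row.seq1.upper())
        s2 = to_array(row.seq2.upper())
        if row.fragment_strand == "+":
            # read1 forward at [start1,end1); read2 reverse-complement of the
            # original-strand tail at [start2,end2); overlap counted from read1
            _count(row.chrom, row.start1, row.end1,
                   lambda p: s1[p - row.start1], "+")
            rc2 = np.array([_COMP_CODE[b] for b in s2[::-1]], dtype=np.uint8)
            lo2 = max(row.start2, row.end1)
            if lo2 < row.end2:
                _count(row.chrom, lo2, row.end2,
                       lambda p: rc2[p - row.start2], "+")
        else:
            # minus-strand fragment: read1 occupies the right end of the
            # fragment, read2 the left; minus-strand base at p comes from
            # seq1 reversed or the complement of seq2
            rev1 = s1[::-1]
            _count(row.chrom, row.start1, row.end1,
                   lambda p: rev1[p - row.start1], "-")
            comp2 = np.array([_COMP_CODE[b] for b in s2], dtype=np.uint8)
            hi2 = min(row.end2, row.start1)
            if row.start2 < hi2:
                _count(row.chrom, row.start2, hi2,
                       lambda p: comp2[p - row.start2], "-")

    frames = []
    for chrom, a in arrs.items():
        for strand, suffix in (("+", "p"), ("-", "m")):
            r_c = acc[chrom][f"rC_{suffix}"]
            r_t = acc[chrom][f"rT_{suffix}"]
            covered = np.nonzero(r_c + r_t)[0]
            if covered.size == 0:
                continue
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": covered,
                "strand": strand,
                "context": _context_codes(a, covered, strand),
                "rC": r_c[covered],
                "rT": r_t[covered],
            }))
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "context", "rC", "rT"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def annotate_context(calls: pd.DataFrame, genome) -> pd.DataFrame:
    """Attach the primary reference context to a (chrom, pos, strand) table."""
    sequences = genome.sequences if hasattr(genome, "sequences") else genome
    out = calls.reset_index(drop=True).copy()
    ctx = np.empty(len(out), dtype=object)
    for chrom, sub in out.groupby("chrom", sort=False):
        arr = to_array(sequences[chrom].upper())
        for strand in ("+", "-"):
            sel = sub[sub.strand == strand]
            if sel.empty:
                continue
            ctx[sel.index.to_numpy()] = _context_codes(
                arr, sel.pos.to_numpy(), strand
            )
    out["context"] = ctx
    return out


def methylation_rate(r_c, r_t):
    """S = rC / (rC + rT); NaN when the site has no informative coverage."""
    r_c = np.asarray(r_c, dtype=float)
    r_t = np.asarray(r_t, dtype=float)
    tot = r_c + r_t
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(tot > 0, r_c / np.where(tot > 0, tot, 1), np.nan)
    return float(s) if s.ndim == 0 else s


def overall_methylation(calls: pd.DataFrame | None = None, r_c=None, r_t=None):
    """Pooled regional MR: ΣrC / (ΣrC + ΣrT), not the mean of per-site rates."""
    if calls is not None:
        r_c, r_t = calls["rC"], calls["rT"]
    total_c = float(np.sum(r_c))
    total_t = float(np.sum(r_t))
    if total_c + total_t == 0:
        return float("nan")
    return total_c / (total_c + total_t)


def combine_cg_strands(calls: pd.DataFrame, genome=None,
                       density_window: int = 600) -> pd.DataFrame:
    """Merge the two cytosines of each CG dinucleotide into one site record.

    The site is keyed by the plus-strand C position.  Per-strand rates Sp
    (sense) and Sn (antisense) are retained for strand analyses alongside
    the pooled rate; strands without coverage contribute nothing to the
    pooled counts and leave their rate NaN.  When ``genome`` is given a
    ``cg_density`` column (CG count within the centred ``density_window``)
    is added.
    """
    cg = calls[calls["context"] == "CG"]
    plus = cg[cg["strand"] == "+"][["chrom", "pos", "rC", "rT"]].rename(
        columns={"rC": "rC_p", "rT": "rT_p"}
    )
    minus = cg[cg["strand"] == "-"][["chrom", "pos", "rC", "rT"]].copy()
    minus["pos"] = minus["pos"] - 1  # anchor at the plus-strand C
    minus = minus.rename(columns={"rC": "rC_n", "rT": "rT_n"})
    merged = plus.merge(minus, on=["chrom", "pos"], how="outer").fillna(0)
    for col in ("rC_p", "rT_p", "rC_n", "rT_n"):
        merged[col] = merged[col].astype(np.int64)
    merged["cov_p"] = merged.rC_p + merged.rT_p
    merged["cov_n"] = merged.rC_n + merged.rT_n
    merged["coverage"] = merged.cov_p + merged.cov_n
    with np.errstate(invalid="ignore"):
        merged["Sp"] = np.where(merged.cov_p > 0,
                                merged.rC_p / merged.cov_p.replace(0, 1), np.nan)
        merged["Sn"] = np.where(merged.cov_n > 0,
                                merged.rC_n / merged.cov_n.replace(0, 1), np.nan)
        merged["S_combined"] = (merged.rC_p + merged.rC_n) / merged.coverage
    merged = merged.sort_values(["chrom", "pos"], ignore_index=True)
    if genome is not None:
        sequences = genome.sequences if hasattr(genome, "sequences") else genome
        dens = np.empty(len(merged), dtype=np.int64)
        for chrom, sub in merged.groupby("chrom", sort=False):
            dens[sub.index.to_numpy()] = cg_density(
                sequences, chrom, sub.pos.to_numpy(), window=density_window
            )
        merged["cg_density"] = dens
    return merged


def cg_density(genome, chrom: str, pos, window: int = 600):
    """CG sites within the ``window``-bp window centred on a CG of interest.

    Counts CG dinucleotides whose plus-strand C lies in
    ``[pos - window/2, pos + window/2]`` inclusive, the focal site included.
    Truncated windows at chromosome ends are counted as-is.
    """
    sequences = genome.sequences if hasattr(genome, "sequences") else genome
    starts = cg_start_positions(sequences[chrom].upper())
    half = window // 2
    p = np.asarray(pos)
    lo = np.searchsorted(starts, p - half, side="left")
    hi = np.searchsorted(starts, p + half, side="right")
    counts = hi - lo
    return int(counts) if counts.ndim == 0 else counts


def write_cx_report(calls: pd.DataFrame, path) -> None:
    """CX-style TSV export (1-based positions): chrom pos strand context rC rT."""
    out = calls.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)
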