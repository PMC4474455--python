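"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written from first principles — exhaustive
scans and enumerations — and shares no search or scanning code with the
package.
"""

from __future__ import annotations

from math import comb

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from acemethylome._seq import c2t, g2a, revcomp, phred_to_q, to_array


def brute_candidates(conv_read, quals, conv_genomes, which_read, params):
    """Full-scan candidate search over every position of both converted genomes.

    ``conv_genomes`` is ``{'C2T': {chrom: seq}, 'G2A': {chrom: seq}}``.
    Applies the same budgets as the aligner: at most
    ``max_mismatch_leading`` mismatches within the read's leading bases and
    a summed quality at mismatches of at most ``max_phred``.  Returns a
    list of (chrom, start, strand, n_leading_mismatches, phred_sum) sorted
    by phred then coordinates, truncated to ``max_hits``.
    """
    if which_read == 1:
        combos = [("C2T", "+", False), ("G2A", "-", True)]
    else:
        combos = [("G2A", "+", False), ("C2T", "-", True)]
    q = phred_to_q(quals)
    n = len(conv_read)
    hits = {}
    for genome_key, strand, reversed_search in combos:
        search = revcomp(conv_read) if reversed_search else conv_read
        search_arr = to_array(search)
        q_search = q[::-1] if reversed_search else q
        for chrom, seq in conv_genomes[genome_key].items():
            garr = to_array(seq)
            if garr.size < n:
                continue
            win = sliding_window_view(garr, n)
            lead_len = min(params.leading_bases, n)
            if reversed_search:
                lead = win[:, n - lead_len:] != search_arr[n - lead_len:]
            else:
                lead = win[:, :lead_len] != search_arr[:lead_len]
            n_lead = lead.sum(axis=1)
            for s in np.nonzero(n_lead <= params.max_mismatch_leading)[0]:
                mism = win[s] != search_arr
                phred = int(q_search[mism].sum())
                if phred <= params.max_phred:
                    hits[(chrom, int(s), strand)] = (
                        chrom, int(s), strand, int(n_lead[s]), phred
                    )
    out = sorted(hits.values(), key=lambda h: (h[4], h[0], h[1], h[2]))
    return out[: params.max_hits]


def brute_resolve(cands1, cands2, len1, len2, window):
    """Independent pair resolution: returns (resolution, chrom, fs, fe, strand).

    cands are tuples as produced by :func:`brute_candidates`.
    """

    def frag(c1, c2):
        chrom1, s1, st1 = c1[0], c1[1], c1[2]
        chrom2, s2, st2 = c2[0], c2[1], c2[2]
        if chrom1 != chrom2:
            return None
        if st1 == "+" and st2 == "-":
            fs, fe, strand = s1, s2 + len2, "+"
        elif st1 == "-" and st2 == "+":
            fs, fe, strand = s2, s1 + len1, "-"
        else:
            return None
        if not window[0] <= fe - fs <= window[1]:
            return None
        return chrom1, fs, fe, strand

    u1, u2 = len(cands1) == 1, len(cands2) == 1
    if u1 and u2:
        f = frag(cands1[0], cands2[0])
        return ("both_unique",) + f if f else ("unresolved", None, None, None, None)
    if u1 ^ u2:
        if u1:
            options = [frag(cands1[0], c) for c in cands2]
        else:
            options = [frag(c, cands2[0]) for c in cands1]
        options = [o for o in options if o]
        if len(options) == 1:
            return ("rescued",) + options[0]
    return ("unresolved", None, None, None, None)


def brute_align_pair(s1, q1, s2, q2, sequences, params):
    """Full brute-force alignment of one read pair."""
    conv_genomes = {
        "C2T": {c: c2t(s) for c, s in sequences.items()},
        "G2A": {c: g2a(s) for c, s in sequences.items()},
    }
    cand1 = brute_candidates(c2t(s1), q1, conv_genomes, 1, params)
    cand2 = brute_candidates(g2a(s2), q2, conv_genomes, 2, params)
    return brute_resolve(cand1, cand2, len(s1), len(s2),
                         (params.fragment_min, params.fragment_max))


def maximal_runs(qualifying, min_run):
    """All maximal runs of True of length >= min_run, as (start_idx, end_idx)
    inclusive, by direct enumeration."""
    runs = []
    i = 0
    n = len(qualifying)
    while i < n:
        if qualifying[i]:
            j = i
            while j + 1 < n and qualifying[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact p-value by hypergeometric enumeration."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c

    def pmf(k):
        return comb(col1, k) * comb(n - col1, row1 - k) / comb(n, row1)

    p_obs = pmf(a)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


def count_cg_in_window(seq, pos, half=300):
    """CG dinucleotides with plus-strand C in [pos-half, pos+half], by scan."""
    n = 0
    for i in range(max(0, pos - half), min(len(seq) - 1, pos + half) + 1):
        if seq[i:i + 2] == "CG":
            n += 1
    return n
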