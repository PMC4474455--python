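"""Three-letter bisulfite paired-end alignment with anchored mate rescue.

The reference is reduced to two converted alphabets (C->T and G->A) and
reads are converted the same way (C->T in read 1, G->A in read 2), so that
bisulfite conversion no longer produces mismatches.  Candidate loci are
found by exact k-mer seeds into the converted genomes and verified against
two budgets applied conjunctively: at most three mismatches within the
leading 40 bases of the read, and a summed base quality of at most 140 at
all mismatched positions.  Up to 20 candidates are retained per read.

A read pair is resolved when both mates align uniquely and concordantly, or
when a uniquely aligned mate rescues its multi-mapping partner: among the
partner's candidates, exactly one must lie on the same chromosome in
convergent orientation with an implied fragment length inside the library's
size-selection window.  Ambiguous rescues are discarded rather than scored,
which avoids biasing coverage toward the reference copy of a repeat.

For a directional library the four orientation searches are: read 1 against
the C->T genome forward and the G->A genome reversed; read 2 against the
G->A genome forward and the C->T genome reversed.  Alignment is ungapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import c2t, g2a, phred_to_q, revcomp, to_array

__all__ = [
    "AlignParams",
    "ConvertedIndex",
    "AlignmentCandidate",
    "PairAlignment",
    "build_index",
    "convert_reads",
    "align_read",
    "resolve_pair",
    "align_pairs",
    "ALIGNMENT_COLUMNS",
]


@dataclass
class AlignParams:
    seed_length: int = 20
    max_mismatch_leading: int = 3
    leading_bases: int = 40
    max_phred: int = 140
    max_hits: int = 20
    fragment_min: int = 300
    fragment_max: int = 600

    def __post_init__(self) -> None:
        if self.seed_length < 12:
            raise ValueError("seed_length must be >= 12")


@dataclass
class ConvertedIndex:
    """Exact k-mer lookup over one converted genome."""

    conversion: str  # 'C2T' or 'G2A'
    seed_length: int
    sequences: dict[str, str]  # converted sequences
    seeds: dict[str, list] = field(repr=False, default_factory=dict)

    def lookup(self, kmer: str) -> list:
        """All (chrom, position) occurrences of a converted k-mer."""
        return self.seeds.get(kmer, [])


@dataclass(frozen=True)
class AlignmentCandidate:
    chrom: str
    start: int  # 0-based leftmost reference coordinate of the match
    strand: str  # '+' read matches the converted genome forward, '-' reversed
    mismatches_leading: int
    phred_mismatch_sum: int


@dataclass
class PairAlignment:
    chrom: str | None
    start1: int | None
    end1: int | None
    start2: int | None
    end2: int | None
    fragment_strand: str | None
    score: int | None  # summed phred_mismatch_sum of both mates; lower is better
    resolution: str  # both_unique | rescued | unresolved


def build_index(
    sequences: dict[str, str], seed_length: int = 20
) -> tuple[ConvertedIndex, ConvertedIndex]:
    """Build the C->T and G->A converted-genome seed indexes."""
    out = []
    for conversion, convert in (("C2T", c2t), ("G2A", g2a)):
        conv_seqs = {}
        seeds: dict[str, list] = {}
        for chrom, seq in sequences.items():
            if len(seq) < seed_length:
                warnings.warn(
                    f"{chrom} shorter than seed_length {seed_length}; skipped"
                )
                continue
            cs = convert(seq.upper())
            conv_seqs[chrom] = cs
            for i in range(len(cs) - seed_length + 1):
                seeds.setdefault(cs[i:i + seed_length], []).append((chrom, i))
        out.append(ConvertedIndex(conversion, seed_length, conv_seqs, seeds))
    return out[0], out[1]


def convert_reads(read1: str, read2: str) -> tuple[str, str]:
    """Apply the read-side alphabet reduction (C->T in read 1, G->A in read 2)."""
    return c2t(read1.upper()), g2a(read2.upper())


def _verify(
    search_seq: np.ndarray,
    quals_search: np.ndarray,
    genome_arr: np.ndarray,
    start: int,
    reversed_search: bool,
    params: AlignParams,
):
    """Check one candidate locus against both budgets.

    ``search_seq``/``quals_search`` are in search orientation; when the
    search string is the reverse complement of the read, the read's leading
    bases are the *trailing* bases of the search string.
    """
    n = search_seq.size
    if start < 0 or start + n > genome_arr.size:
        return None
    window = genome_arr[start:start + n]
    mism = window != search_seq
    if not mism.any():
        return 0, 0
    if reversed_search:
        lead = mism[::-1][: params.leading_bases]
    else:
        lead = mism[: params.leading_bases]
    n_lead = int(lead.sum())
    if n_lead > params.max_mismatch_leading:
        return None
    phred = int(quals_search[mism].sum())
    if phred > params.max_phred:
        return None
    return n_lead, phred


def _seed_offsets(read_len: int, k: int, budget: int) -> list[int]:
    """Non-overlapping seed offsets; budget+1 seeds guarantee one exact seed
    whenever the total mismatch count is within the budget."""
    n_seeds = budget + 1
    offs = [i * k for i in range(n_seeds) if i * k + k <= read_len]
    if not offs:
        offs = [0]
    last = read_len - k
    if last not in offs and last > offs[-1]:
        offs.append(last)
    return offs


def align_read(
    conv_read: str,
    quals: str,
    indexes: tuple[ConvertedIndex, ConvertedIndex],
    which_read: int,
    params: AlignParams | None = None,
) -> list[AlignmentCandidate]:
    """All candidate loci of one converted mate, best (lowest phred sum) first.

    ``which_read`` is 1 or 2 and selects the directional-protocol search
    combinations.  At most ``max_hits`` candidates are returned; uniqueness
    downstream means exactly one candidate passed the budgets.
    """
    params = params or AlignParams()
    c2t_idx, g2a_idx = indexes
    if which_read == 1:
        combos = [(c2t_idx, "+", False), (g2a_idx, "-", True)]
    elif which_read == 2:
        combos = [(g2a_idx, "+", False), (c2t_idx, "-", True)]
    else:
        raise ValueError("which_read must be 1 or 2")

    q = phred_to_q(quals)
    n = len(conv_read)
    k = params.seed_length
    if n < k:
        return []
    found: dict[tuple, AlignmentCandidate] = {}
    for index, strand, reversed_search in combos:
        search = conv_read if not reversed_search else revcomp(conv_read)
        search_arr = to_array(search)
        q_search = q if not reversed_search else q[::-1]
        genome_arrs = {c: to_array(s) for c, s in index.sequences.items()}
        seen = set()
        for off in _seed_offsets(n, k, params.max_mismatch_leading):
            for chrom, pos in index.lookup(search[off:off + k]):
                start = pos - off
                key = (chrom, start)
                if key in seen:
                    continue
                seen.add(key)
                res = _verify(
                    search_arr, q_search, genome_arrs[chrom], start,
                    reversed_search, params,
                )
                if res is not None:
                    found[(chrom, start, strand)] = AlignmentCandidate(
                        chrom, start, strand, res[0], res[1]
                    )
    cands = sorted(
        found.values(),
        key=lambda c: (c.phred_mismatch_sum, c.chrom, c.start, c.strand),
    )
    return cands[: params.max_hits]


def _concordant(c1, c2, len1, len2, window):
    """Fragment coordinates if two mate candidates form a convergent pair."""
    if c1.chrom != c2.chrom:
        return None
    if c1.strand == "+" and c2.strand == "-":
        fs, fe, strand = c1.start, c2.start + len2, "+"
    elif c1.strand == "-" and c2.strand == "+":
        fs, fe, strand = c2.start, c1.start + len1, "-"
    else:
        return None
    frag_len = fe - fs
    if frag_len < window[0] or frag_len > window[1]:
        return None
    return fs, fe, strand


def resolve_pair(
    cands1: list[AlignmentCandidate],
    cands2: list[AlignmentCandidate],
    len1: int,
    len2: int,
    fragment_window: tuple[int, int] = (300, 600),
) -> PairAlignment:
    """Resolve a mate pair by concordance or anchored rescue.

    Both mates unique and concordant -> ``both_unique``.  Exactly one mate
    unique -> among the partner's candidates, the ones concordant with the
    anchor inside the fragment window are enumerated; exactly one survivor
    -> ``rescued``, otherwise the pair is ``unresolved`` (discarded).
    """
    u1, u2 = len(cands1) == 1, len(cands2) == 1

    def _build(c1, c2, resolution):
        frag = _concordant(c1, c2, len1, len2, fragment_window)
        if frag is None:
            return PairAlignment(None, None, None, None, None, None, None,
                                 "unresolved")
        fs, fe, strand = frag
        return PairAlignment(
            c1.chrom, c1.start, c1.start + len1, c2.start, c2.start + len2,
            strand, c1.phred_mismatch_sum + c2.phred_mismatch_sum, resolution,
        )

    if u1 and u2:
        return _build(cands1[0], cands2[0], "both_unique")
    if u1 != u2 and (u1 or u2):
        anchor, partners = (cands1[0], cands2) if u1 else (cands2[0], cands1)
        survivors = []
        for c in partners:
            pair = (anchor, c) if u1 else (c, anchor)
            if _concordant(pair[0], pair[1], len1, len2, fragment_window):
                survivors.append(c)
        if len(survivors) == 1:
            c1, c2 = (anchor, survivors[0]) if u1 else (survivors[0], anchor)
            return _build(c1, c2, "rescued")
    return PairAlignment(None, None, None, None, None, None, None, "unresolved")


ALIGNMENT_COLUMNS = [
    "read_id", "chrom", "start1", "end1", "start2", "end2",
    "frag_start", "frag_end", "fragment_strand", "score", "resolution",
    "seq1", "seq2",
]


def align_pairs(
    reads1,
    reads2,
    indexes: tuple[ConvertedIndex, ConvertedIndex],
    params: AlignParams | None = None,
) -> pd.DataFrame:
    """Align a list of read pairs, returning the resolved alignment table.

    ``reads1``/``reads2`` are parallel lists of ``(read_id, seq, qual)``.
    The original (unconverted) read sequences are carried through for
    methylation calling.  Unresolved pairs are kept with a null chromosome
    so callers can report mapping efficiency; downstream stages drop them.
    """
    params = params or AlignParams()
    window = (params.fragment_min, params.fragment_max)
    rows = []
    for (rid1, s1, q1), (rid2, s2, q2) in zip(reads1, reads2):
        conv1, conv2 = convert_reads(s1, s2)
        c1 = align_read(conv1, q1, indexes, 1, params)
        c2 = align_read(conv2, q2, indexes, 2, params)
        pair = resolve_pair(c1, c2, len(s1), len(s2), window)
        if pair.resolution == "unresolved":
            rows.append((rid1, None, -1, -1, -1, -1, -1, -1, ".",
                         -1, "unresolved", s1, s2))
        else:
            rows.append((
                rid1, pair.chrom, pair.start1, pair.end1, pair.start2,
                pair.end2, min(pair.start1, pair.start2),
                max(pair.end1, pair.end2), pair.fragment_strand, pair.score,
                pair.resolution, s1, s2,
            ))
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
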