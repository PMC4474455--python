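"""Synthetic bisulfite-sequencing study generator.

Builds toy genomes with gene / LINE / LTR features and CpG islands, assigns
genotype-specific per-cytosine methylation probabilities (wild type and DNMT
knockouts), and simulates directional paired-end bisulfite libraries with
sonication-sized fragments, incomplete conversion, and per-fragment PCR
amplification — together with a ground-truth table so every downstream stage
of the pipeline can be validated without external data.

Coordinates are 0-based half-open throughout.  A cytosine record is keyed by
the position of the interrogated base on the plus strand: for a minus-strand
cytosine that is the position of the plus-strand G.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import (
    A,
    C,
    G,
    T,
    from_array,
    revcomp_array,
    to_array,
)

__all__ = [
    "FeatureSpec",
    "ToyGenomeSpec",
    "ToyGenome",
    "MethylomeProfile",
    "LibraryParams",
    "Fragment",
    "ReadSim",
    "LayoutError",
    "generate_toy_genome",
    "default_profile",
    "assign_methylome",
    "simulate_bsseq_reads",
    "truth_pileup",
    "sample_counts",
    "simulate_expression",
]

# Target CG-dinucleotide counts per 600-bp window for the two density classes:
# "low" emulates methylation-prone low-density sequence, "high" a CpG island.
DENSITY_BY_CLASS = {"low": 24.0, "high": 60.0}

_FEATURE_KINDS = ("gene", "LINE", "LTR")
_DEFAULT_FAMILY = {"LINE": "L1", "LTR": "ERVK", "gene": "."}


class LayoutError(ValueError):
    """A declared feature layout does not fit inside its chromosome."""


@dataclass
class FeatureSpec:
    """One genomic feature to embed in the toy genome.

    ``chrom`` (0-based chromosome index) and ``start`` may be left ``None``
    to have the feature placed automatically on chromosome 0 with spacer
    sequence between consecutive features.
    """

    kind: str
    subtype: str = ""
    length: int = 1000
    strand: str = "+"
    cg_density_class: str = "low"
    family: str | None = None
    chrom: int | None = None
    start: int | None = None
    # genes only: extra upstream sequence synthesized with the gene's CG
    # density and methylation class, so a TSS-centred promoter window stays
    # within gene-class territory; the annotated interval excludes the pad
    promoter_pad: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "LTR" and self.length < 300:
            raise ValueError("LTR features must be at least 300 bp")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.cg_density_class not in DENSITY_BY_CLASS:
            raise ValueError(f"unknown cg_density_class {self.cg_density_class!r}")
        if self.family is None:
            self.family = _DEFAULT_FAMILY[self.kind]
        if not self.subtype:
            self.subtype = {"LINE": "L1Md_A", "LTR": "IAP-like", "gene": "gene"}[self.kind]


@dataclass
class ToyGenomeSpec:
    n_chromosomes: int = 1
    chrom_length: int = 50_000
    gc_fraction: float = 0.42
    cg_island_spec: list[tuple[int, float]] = field(default_factory=list)
    feature_layout: list[FeatureSpec] = field(default_factory=list)
    spacer: int = 700  # gap left between auto-placed intervals

    def __post_init__(self) -> None:
        if self.chrom_length < 10_000:
            raise ValueError("chrom_length must be >= 10,000")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must lie in (0, 1)")


@dataclass
class ToyGenome:
    """A generated genome plus its annotation tables (BED-like frames)."""

    sequences: dict[str, str]
    repeats: pd.DataFrame  # chrom start end name score strand family class cg_class
    genes: pd.DataFrame  # chrom start end name score strand cg_class
    islands: pd.DataFrame  # chrom start end target_density


def _region(length: int, cg_per_600: float, gc_fraction: float, rng) -> np.ndarray:
    """Random sequence of `length` with an exactly controlled CG count.

    Bases are drawn iid at the requested GC fraction, every spontaneous CG
    dinucleotide is destroyed, and the target number of CGs is planted at
    even offsets so the realized count equals ``round(length * d / 600)``.
    """
    if length <= 0:
        return np.empty(0, dtype=np.uint8)
    gc = gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = np.array([A, C, G, T], dtype=np.uint8)[rng.choice(4, size=length, p=probs)]
    if length >= 2:
        spontaneous = np.nonzero((arr[:-1] == C) & (arr[1:] == G))[0]
        arr[spontaneous + 1] = A
        n_cg = int(round(length * cg_per_600 / 600.0))
        slots = np.arange(0, length - 1, 2)
        n_cg = min(n_cg, slots.size)
        if n_cg:
            starts = rng.choice(slots, size=n_cg, replace=False)
            arr[starts] = C
            arr[starts + 1] = G
    return arr


def generate_toy_genome(spec: ToyGenomeSpec, seed: int):
    """Emit a toy genome honouring the declared feature layout.

    Returns a :class:`ToyGenome`.  Deterministic for a fixed seed.  Raises
    :class:`LayoutError` when intervals cannot fit within the chromosome.
    """
    rng = np.random.default_rng(seed)
    L = spec.chrom_length
    gap = spec.spacer
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    bg_density = 600.0 * (spec.gc_fraction / 2.0) ** 2

    # resolve placements: (chrom_idx, start, end, payload)
    placements: list[tuple[int, int, int, object]] = []
    cursors = {i: gap for i in range(spec.n_chromosomes)}

    def _place(ci, start, length, payload):
        if start is None:
            ci = 0 if ci is None else ci
            start = cursors[ci]
            cursors[ci] = start + length + gap
        ci = 0 if ci is None else ci
        end = start + length
        if ci >= spec.n_chromosomes:
            raise LayoutError(f"feature assigned to nonexistent chromosome {ci}")
        if start < 0 or end > L:
            raise LayoutError(
                f"interval [{start}, {end}) exceeds chromosome of length {L}"
            )
        placements.append((ci, start, end, payload))

    for feat in spec.feature_layout:
        pad = feat.promoter_pad if feat.kind == "gene" else 0
        _place(feat.chrom, feat.start, feat.length + pad, feat)
    for isl_len, isl_density in spec.cg_island_spec:
        _place(None, None, isl_len, ("island", isl_density))

    # partial overlaps are layout errors; full containment (nesting) is allowed
    for ci in range(spec.n_chromosomes):
        ivals = sorted((s, e) for c, s, e, _ in placements if c == ci)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1 and e2 > e1:
                raise LayoutError(
                    f"features overlap without nesting: [{s1},{e1}) vs [{s2},{e2})"
                )

    sequences: dict[str, str] = {}
    for ci, name in enumerate(chrom_names):
        arr = _region(L, bg_density, spec.gc_fraction, rng)
        for c, s, e, payload in placements:
            if c != ci:
                continue
            if isinstance(payload, FeatureSpec):
                d = DENSITY_BY_CLASS[payload.cg_density_class]
            else:
                d = payload[1]
            arr[s:e] = _region(e - s, d, spec.gc_fraction, rng)
        sequences[name] = from_array(arr)

    rep_rows, gene_rows, isl_rows = [], [], []
    for c, s, e, payload in placements:
        chrom = chrom_names[c]
        if isinstance(payload, FeatureSpec):
            f = payload
            if f.kind == "gene":
                pad = f.promoter_pad
                gs, ge = (s + pad, e) if f.strand == "+" else (s, e - pad)
                gene_rows.append(
                    (chrom, gs, ge, f.subtype, 0, f.strand,
                     f.cg_density_class, pad)
                )
            else:
                rep_rows.append(
                    (chrom, s, e, f.subtype, 0, f.strand, f.family, f.kind,
                     f.cg_density_class)
                )
        else:
            isl_rows.append((chrom, s, e, payload[1]))

    repeats = pd.DataFrame(
        rep_rows,
        columns=["chrom", "start", "end", "name", "score", "strand", "family",
                 "class", "cg_class"],
    )
    genes = pd.DataFrame(
        gene_rows,
        columns=["chrom", "start", "end", "name", "score", "strand",
                 "cg_class", "promoter_pad"],
    )
    if not genes.empty:
        genes["name"] = [f"gene{i}" for i in range(len(genes))]
    islands = pd.DataFrame(isl_rows, columns=["chrom", "start", "end",
                                              "target_density"])
    for df in (repeats, genes, islands):
        if not df.empty:
            df.sort_values(["chrom", "start"], inplace=True, ignore_index=True)
    return ToyGenome(sequences, repeats, genes, islands)


# ---------------------------------------------------------------------------
# methylome assignment
# ---------------------------------------------------------------------------

@dataclass
class MethylomeProfile:
    """Per-region CG methylation probabilities for one genotype.

    ``region_probs`` maps a region class to a probability.  Recognised keys:
    ``background``, ``cg_island``, ``LTR``, ``LINE_promoter``, ``LINE_body``,
    ``gene:low``, ``gene:high`` (falling back to ``gene`` then
    ``background``).  Under ``strand_mode='symmetric'`` both cytosines of a
    CG dinucleotide share one probability; under ``'independent'`` each
    strand independently adopts the high or low level of
    ``independent_levels`` with the class probability acting as the mixing
    weight.
    """

    genotype: str
    region_probs: dict[str, float]
    strand_mode: str = "symmetric"
    chh_rate: float = 0.0
    independent_levels: tuple[float, float] = (0.9, 0.02)

    def __post_init__(self) -> None:
        if self.strand_mode not in ("symmetric", "independent"):
            raise ValueError("strand_mode must be 'symmetric' or 'independent'")
        for k, v in self.region_probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"probability for {k!r} outside [0,1]")
        if not 0.0 <= self.chh_rate <= 1.0:
            raise ValueError("chh_rate outside [0,1]")
        if self.genotype == "TKO":
            bad = {k: v for k, v in self.region_probs.items() if v > 0.01}
            if bad or self.chh_rate > 0.01:
                raise ValueError("TKO probabilities must not exceed 0.01")

    def prob_for(self, region_class: str) -> float:
        probs = self.region_probs
        if region_class in probs:
            return probs[region_class]
        if region_class.startswith("gene") and "gene" in probs:
            return probs["gene"]
        if "background" in probs:
            return probs["background"]
        raise KeyError(f"no probability configured for region class {region_class!r}")


# Default genotype profiles.  Wild type is heavily methylated outside CpG
# islands; the DNMT1 knockout (1KO) loses maintenance methylation except at
# LINE promoters; the DNMT3a/3b double knockout (DKO) retains methylation at
# LTR-like elements; the triple knockout is essentially unmethylated.
_DEFAULT_PROFILES = {
    "WT": dict(background=0.78, cg_island=0.02, LTR=0.85, LINE_promoter=0.85,
               LINE_body=0.78, **{"gene:low": 0.75, "gene:high": 0.02}),
    "1KO": dict(background=0.18, cg_island=0.01, LTR=0.18, LINE_promoter=0.78,
                LINE_body=0.18, **{"gene:low": 0.15, "gene:high": 0.01}),
    "DKO": dict(background=0.18, cg_island=0.01, LTR=0.78, LINE_promoter=0.18,
                LINE_body=0.18, **{"gene:low": 0.15, "gene:high": 0.01}),
    "TKO": dict(background=0.005, cg_island=0.005, LTR=0.005,
                LINE_promoter=0.005, LINE_body=0.005,
                **{"gene:low": 0.005, "gene:high": 0.005}),
}
_DEFAULT_CHH = {"WT": 0.01, "1KO": 0.02, "DKO": 0.0, "TKO": 0.0}


def default_profile(genotype: str, strand_mode: str = "symmetric") -> MethylomeProfile:
    """Built-in methylome profile for WT / 1KO / DKO / TKO."""
    if genotype not in _DEFAULT_PROFILES:
        raise KeyError(f"unknown genotype {genotype!r}")
    return MethylomeProfile(
        genotype=genotype,
        region_probs=dict(_DEFAULT_PROFILES[genotype]),
        strand_mode=strand_mode,
        chh_rate=_DEFAULT_CHH[genotype],
    )


def _region_class_array(genome: ToyGenome, chrom: str, length: int) -> np.ndarray:
    """Per-base region class labels for one chromosome."""
    classes = np.array(["background"] * length, dtype=object)
    isl = genome.islands
    for _, r in isl[isl.chrom == chrom].iterrows():
        classes[int(r.start):int(r.end)] = "cg_island"
    gn = genome.genes
    for _, r in gn[gn.chrom == chrom].iterrows():
        pad = int(r.get("promoter_pad", 0) or 0)
        if r.strand == "+":
            s, e = int(r.start) - pad, int(r.end)
        else:
            s, e = int(r.start), int(r.end) + pad
        classes[max(0, s):e] = f"gene:{r.get('cg_class', 'low')}"
    rp = genome.repeats
    for _, r in rp[rp.chrom == chrom].iterrows():
        s, e = int(r.start), int(r.end)
        if r["class"] == "LTR":
            classes[s:e] = "LTR"
        elif r["class"] == "LINE":
            classes[s:e] = "LINE_body"
            if r.strand == "+":
                ps, pe = max(0, s - 100), min(length, s + 1000)
            else:
                ps, pe = max(0, e - 1000), min(length, e + 100)
            classes[ps:pe] = "LINE_promoter"
    return classes


def assign_methylome(
    genome: ToyGenome,
    profile: MethylomeProfile,
    seed: int,
    contexts: tuple[str, ...] = ("CG", "CHG", "CHH"),
) -> pd.DataFrame:
    """Per-cytosine methylation probability table.

    Returns a frame with columns ``chrom, pos, strand, context, prob``
    covering every cytosine on both strands whose context is in
    ``contexts``.  CG probabilities come from the enclosing region class
    (looked up at the plus-strand C so both strands of a dinucleotide see
    the same class); non-CG cytosines take ``profile.chh_rate``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, seq in genome.sequences.items():
        arr = to_array(seq)
        n = arr.size
        classes = _region_class_array(genome, chrom, n)
        uniq = sorted(set(classes.tolist()))
        probs_by_class = {u: profile.prob_for(u) for u in uniq}
        class_p = np.array([probs_by_class[c] for c in classes])

        # plus-strand cytosines
        pos_p = np.nonzero(arr == C)[0]
        nxt = np.full(n, A, dtype=np.uint8)
        nxt[:-1] = arr[1:]
        nxt2 = np.full(n, A, dtype=np.uint8)
        nxt2[:-2] = arr[2:]
        ctx_p = np.where(nxt[pos_p] == G, "CG",
                         np.where(nxt2[pos_p] == G, "CHG", "CHH"))
        # minus-strand cytosines (plus-strand G positions)
        pos_m = np.nonzero(arr == G)[0]
        prv = np.full(n, T, dtype=np.uint8)
        prv[1:] = arr[:-1]
        prv2 = np.full(n, T, dtype=np.uint8)
        prv2[2:] = arr[:-2]
        ctx_m = np.where(prv[pos_m] == C, "CG",
                         np.where(prv2[pos_m] == C, "CHG", "CHH"))

        prob_p = np.where(ctx_p == "CG", class_p[pos_p], profile.chh_rate)
        # a minus-strand CG cytosine takes the class of its plus-strand partner
        anchor_m = np.where(ctx_m == "CG", np.maximum(pos_m - 1, 0), pos_m)
        prob_m = np.where(ctx_m == "CG", class_p[anchor_m], profile.chh_rate)

        if profile.strand_mode == "independent":
            hi, lo = profile.independent_levels
            cg_p = ctx_p == "CG"
            cg_m = ctx_m == "CG"
            prob_p = prob_p.copy()
            prob_m = prob_m.copy()
            prob_p[cg_p] = np.where(rng.random(cg_p.sum()) < prob_p[cg_p], hi, lo)
            prob_m[cg_m] = np.where(rng.random(cg_m.sum()) < prob_m[cg_m], hi, lo)

        for pos, strand, ctx, prob in (
            (pos_p, "+", ctx_p, prob_p),
            (pos_m, "-", ctx_m, prob_m),
        ):
            keep = np.isin(ctx, contexts)
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": pos[keep],
                "strand": strand,
                "context": ctx[keep],
                "prob": prob[keep],
            }))
    out = pd.concat(frames, ignore_index=True)
    out.sort_values(["chrom", "pos", "strand"], inplace=True, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class LibraryParams:
    """Directional paired-end bisulfite library parameters.

    ``depth`` is the target mean per-base read coverage (each fragment
    contributes two reads of ``read_length``).  ``pcr_bias`` maps a fragment
    to its amplification factor: either a dict keyed by fragment index or a
    callable ``f(fragment) -> int``; ``None`` means no amplification.
    """

    fragment_min: int = 300
    fragment_max: int = 600
    read_length: int = 80
    conversion_rate: float = 0.99
    pcr_bias: object = None
    depth: float = 30.0
    seed: int = 0
    error_rate: float = 0.0
    base_quality: int = 40

    def __post_init__(self) -> None:
        if self.fragment_min >= self.fragment_max:
            raise ValueError("fragment_min must be < fragment_max")
        if not 0.95 < self.conversion_rate <= 1.0:
            raise ValueError("conversion_rate must lie in (0.95, 1]")
        if self.read_length > self.fragment_min:
            raise ValueError("read_length must not exceed fragment_min")


@dataclass
class Fragment:
    """An explicit sonication fragment (for scripted scenarios)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    copies: int = 1
    meth: dict[int, bool] = field(default_factory=dict)  # pos -> methylated


@dataclass
class ReadSim:
    """Simulated read set plus its ground truth.

    ``reads1``/``reads2`` are lists of ``(read_id, sequence, quality)``.
    ``fragments`` records one row per sonication fragment with its copy
    number; ``states`` records the post-conversion base (C or T) observed at
    every cytosine of every fragment's original strand.
    """

    reads1: list[tuple[str, str, str]]
    reads2: list[tuple[str, str, str]]
    fragments: pd.DataFrame  # fragment_id chrom start end strand copies
    states: pd.DataFrame  # fragment_id chrom pos strand state


def _prob_arrays(sequences: dict[str, str], probs: pd.DataFrame):
    out = {}
    for chrom, seq in sequences.items():
        n = len(seq)
        pp = np.zeros(n)
        pm = np.zeros(n)
        sub = probs[probs.chrom == chrom]
        plus = sub[sub.strand == "+"]
        minus = sub[sub.strand == "-"]
        pp[plus.pos.to_numpy()] = plus.prob.to_numpy()
        pm[minus.pos.to_numpy()] = minus.prob.to_numpy()
        out[chrom] = (pp, pm)
    return out


def simulate_bsseq_reads(
    genome,
    probs: pd.DataFrame,
    lib: LibraryParams,
    fragments: list[Fragment] | None = None,
) -> ReadSim:
    """Simulate a directional paired-end bisulfite library.

    Fragments are drawn uniformly along each chromosome with lengths uniform
    on ``[fragment_min, fragment_max]`` unless an explicit fragment list is
    given.  On each fragment every original-strand cytosine is methylated
    with its assigned probability (or a per-fragment override); unmethylated
    cytosines read as T with probability ``conversion_rate``.  Read 1
    reports the converted original strand, read 2 its reverse complement.
    PCR amplification emits whole-fragment copies before read emission.
    """
    sequences = genome.sequences if isinstance(genome, ToyGenome) else genome
    rng = np.random.default_rng(lib.seed)
    prob_arrays = _prob_arrays(sequences, probs)
    rl = lib.read_length
    qual = chr(33 + lib.base_quality) * rl

    if fragments is None:
        fragments = []
        for chrom, seq in sequences.items():
            n = len(seq)
            n_frag = max(1, int(round(lib.depth * n / (2.0 * rl))))
            lens = rng.integers(lib.fragment_min, lib.fragment_max + 1, n_frag)
            lens = np.minimum(lens, n)
            starts = rng.integers(0, n - lens + 1)
            strands = np.where(rng.random(n_frag) < 0.5, "+", "-")
            for s, ln, st in zip(starts, lens, strands):
                fragments.append(Fragment(chrom, int(s), int(s + ln), str(st)))

    reads1, reads2, frag_rows, state_rows = [], [], [], []
    for fi, frag in enumerate(fragments):
        seq_arr = to_array(sequences[frag.chrom])
        pp, pm = prob_arrays[frag.chrom]
        s, e = frag.start, frag.end
        if frag.strand == "+":
            seg = seq_arr[s:e].copy()
            c_rel = np.nonzero(seg == C)[0]
            c_abs = c_rel + s
            p = pp[c_abs]
        else:
            seg = revcomp_array(seq_arr[s:e]).copy()
            c_rel = np.nonzero(seg == C)[0]
            c_abs = (e - 1) - c_rel  # plus-strand G position of each minus-strand C
            p = pm[c_abs]
        meth = rng.random(c_rel.size) < p
        for k, pos in enumerate(c_abs):
            if int(pos) in frag.meth:
                meth[k] = frag.meth[int(pos)]
        converted = (~meth) & (rng.random(c_rel.size) < lib.conversion_rate)
        seg[c_rel[converted]] = T

        copies = frag.copies
        if lib.pcr_bias is not None:
            if callable(lib.pcr_bias):
                copies = int(lib.pcr_bias(frag))
            else:
                copies = int(lib.pcr_bias.get(fi, frag.copies))
        if copies < 1:
            raise ValueError("amplification factors must be >= 1")

        r1 = seg[:rl]
        r2 = revcomp_array(seg)[:rl]
        if lib.error_rate > 0:
            lut = np.array([A, C, G, T], dtype=np.uint8)
            idx_of = {A: 0, C: 1, G: 2, T: 3}
            for r in (r1, r2):
                hits = np.nonzero(rng.random(min(rl, r.size)) < lib.error_rate)[0]
                if hits.size:
                    shift = rng.integers(1, 4, hits.size)
                    base_idx = np.array([idx_of[b] for b in r[hits]])
                    r[hits] = lut[(base_idx + shift) % 4]
        s1, s2 = from_array(r1), from_array(r2)
        fid = f"f{fi}"
        for ci in range(copies):
            rid = f"{fid}:{ci}"
            reads1.append((rid, s1, qual))
            reads2.append((rid, s2, qual))
        frag_rows.append((fid, frag.chrom, s, e, frag.strand, copies))
        state = np.where(meth | ~converted, "C", "T")
        for pos, st in zip(c_abs, state):
            state_rows.append((fid, frag.chrom, int(pos), frag.strand, st))

    fragments_df = pd.DataFrame(
        frag_rows, columns=["fragment_id", "chrom", "start", "end", "strand",
                            "copies"]
    )
    states_df = pd.DataFrame(
        state_rows, columns=["fragment_id", "chrom", "pos", "strand", "state"]
    )
    return ReadSim(reads1, reads2, fragments_df, states_df)


def truth_pileup(sim: ReadSim, level: str = "clone") -> pd.DataFrame:
    """Cytosine counts from the simulator's ground truth.

    ``level='clone'`` counts each fragment once (the ideal, PCR-free
    pileup); ``level='tag'`` weights each fragment by its amplification
    factor, reproducing what a pileup of all emitted read pairs would see
    if every read covered its whole fragment.
    """
    if level not in ("clone", "tag"):
        raise ValueError("level must be 'clone' or 'tag'")
    df = sim.states.merge(
        sim.fragments[["fragment_id", "copies"]], on="fragment_id"
    )
    w = df.copies.to_numpy() if level == "tag" else np.ones(len(df), dtype=int)
    df = df.assign(
        rC=np.where(df.state == "C", w, 0),
        rT=np.where(df.state == "T", w, 0),
    )
    out = (
        df.groupby(["chrom", "pos", "strand"], as_index=False)[["rC", "rT"]]
        .sum()
        .sort_values(["chrom", "pos", "strand"], ignore_index=True)
    )
    return out


def sample_counts(
    probs: pd.DataFrame,
    mean_coverage: float,
    seed: int,
    conversion_rate: float = 1.0,
) -> pd.DataFrame:
    """Draw per-cytosine read counts directly from assigned probabilities.

    A fast stand-in for full read simulation plus perfect alignment: each
    cytosine-strand receives Poisson(mean_coverage) reads of which
    Binomial(cov, p_eff) retain C, where p_eff folds in incomplete
    conversion.  Rows with zero coverage are dropped, mirroring a pileup.
    """
    rng = np.random.default_rng(seed)
    cov = rng.poisson(mean_coverage, len(probs))
    p = probs.prob.to_numpy()
    p_eff = p + (1.0 - p) * (1.0 - conversion_rate)
    r_c = rng.binomial(cov, p_eff)
    out = probs.copy()
    out["rC"] = r_c
    out["rT"] = cov - r_c
    return out[cov > 0].reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    genes: pd.DataFrame,
    probs: pd.DataFrame,
    seed: int,
    meth_cutoff: float = 0.5,
    density_cutoff: float = 30.0,
    fc_magnitude: tuple[float, float] = (2.7, 5.5),
    p_up: float = 0.85,
) -> pd.DataFrame:
    """FPKM table for WT and TKO driven by promoter methylation.

    Genes whose WT promoter (TSS±500 bp) mean CG methylation probability is
    at least ``meth_cutoff`` and whose promoter CG density (CG count in the
    600-bp window centred on the TSS) is below ``density_cutoff`` are
    silenced in WT and deregulated in TKO with |log2 fold change| above the
    lower bound of ``fc_magnitude`` (mostly up-regulated, a minority
    down-regulated); all other genes receive a fold change near zero.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cg = probs[(probs.context == "CG") & (probs.strand == "+")]
    by_chrom = {
        ch: (sub.pos.to_numpy(), sub.prob.to_numpy())
        for ch, sub in cg.groupby("chrom", sort=False)
    }
    for _, g in genes.iterrows():
        tss = int(g.start) if g.strand == "+" else int(g.end) - 1
        pos, pr = by_chrom.get(g.chrom, (np.empty(0, dtype=int), np.empty(0)))
        lo, hi = np.searchsorted(pos, [tss - 500, tss + 501])
        meth = float(pr[lo:hi].mean()) if hi > lo else 0.0
        dlo, dhi = np.searchsorted(pos, [tss - 300, tss + 301])
        density = int(dhi - dlo)
        deregulated = meth >= meth_cutoff and density < density_cutoff
        if deregulated:
            fc = float(rng.uniform(*fc_magnitude))
            if rng.random() < p_up:
                wt = float(rng.lognormal(0.3, 0.7)) + 0.05
            else:
                fc = -fc
                wt = float(rng.lognormal(2.5, 0.7)) + 1.0
        else:
            fc = float(np.clip(rng.normal(0.0, 0.15), -0.45, 0.45))
            wt = float(rng.lognormal(2.0, 1.2)) + 0.05
        tko = wt * 2.0 ** fc
        rows.append((g["name"], wt, tko, meth, density,
                     "deregulated" if deregulated else "unchanged"))
    return pd.DataFrame(
        rows,
        columns=["gene", "fpkm_wt", "fpkm_tko", "promoter_meth",
                 "promoter_cg_density", "true_class"],
    )
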