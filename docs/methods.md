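# Methods

This note documents the models, conventions, and design choices behind
`acemethylome`. Coordinates are 0-based half-open everywhere except the
CX-style export, which is 1-based. A cytosine record is keyed by the
position of the interrogated base on the plus strand; for a minus-strand
cytosine that is the plus-strand G of the dinucleotide.

## Bisulfite chemistry and the three-letter scheme

Bisulfite converts unmethylated cytosine to uracil (sequenced as T) while
5-methylcytosine is protected. A directional (Lister-style) paired-end
library is modeled: read 1 reports the bisulfite-converted original strand
of a fragment, read 2 its reverse complement. Conversion is incomplete
with probability `1 − conversion_rate` (default 0.99, valid range
(0.95, 1]); an unconverted unmethylated C is indistinguishable from a
methylated one, which biases rates upward by about `(1−p)(1−c)` — below
0.3 % at the default and negligible against counting noise at the
coverages used here.

Alignment reduces both reference and reads to three-letter alphabets: the
C→T genome and the G→A genome. For a directional protocol only four
orientation searches exist, and they are the ones implemented: read 1 vs
the C→T genome forward and the G→A genome reversed; read 2 vs the G→A
genome forward and the C→T genome reversed. (A C-depleted read 1 arising
from the bottom bisulfite strand matches the reverse complement of the
G-depleted reference, not of the C-depleted one; the pairing above follows
from writing out the complement of a converted strand.)

## Candidate search and budgets

Candidate loci come from exact k-mer seeds (default k = 20, minimum 12)
into the converted genomes, at `budget+1` non-overlapping offsets plus the
read tail. By pigeonhole, a locus with at most 3 total mismatches is
always recovered for reads of ≥ 4k bases; at the simulator's default base
quality (Q40) the summed-quality budget caps total mismatches at 3, so on
toy genomes the seeded search is exhaustive and is tested for exact
agreement against a full-scan brute-force aligner. With lower qualities
(more than `n_seeds − 1` tolerable mismatches) the search becomes a
heuristic, as in any seed-and-extend aligner.

Two budgets are applied conjunctively to each candidate: at most 3
mismatches within the leading 40 bases of the read (the read's own 5'
end, also when the search string is reverse-complemented), and a summed
Phred quality at all mismatched positions of at most 140. At most 20
candidates are kept, ranked by ascending quality-weighted mismatch sum. A
mate is *unique* when exactly one candidate passes. Alignment is ungapped;
indels are out of scope.

## Pair resolution and anchored rescue

A pair resolves as `both_unique` when both mates are unique, on one
chromosome, convergent, with implied fragment length inside the library
window (default [300, 600] bp, matching the simulated size selection).
When exactly one mate is unique it anchors a rescue: among the partner's
candidates, those concordant with the anchor inside the window are
enumerated, and the pair is `rescued` only if exactly one survives.
Several survivors mean the fragment length cannot distinguish repeat
copies, and the pair is discarded rather than resolved by score — choosing
the best-scoring copy would systematically favor the reference-like copy
of a repeat family. The pair score (used only for duplicate collapse) is
the summed quality-weighted mismatch count of both mates, lower better.

## Monoclonization

Sonication breaks chromosomes at effectively random positions, so two
independent molecules essentially never share both fragment ends. All
resolved pairs with identical (chromosome, fragment start, fragment end,
bisulfite strand) are therefore PCR copies of one molecule and are
collapsed to the single best-scoring pair; ties break on the
lexicographically first read identifier so the operation is deterministic
and idempotent. The strand is part of the key because methylation is
called per strand and the two strands of one locus are distinct
observations. The operation converts a amplification-weighted ("tag")
pileup into a molecule-level ("clone") pileup: in the canonical
three-fragment scenario (two methylated molecules amplified 10× each, one
unmethylated amplified 50×) the top-strand rate moves from 20/70 ≈ 0.29
back to 2/3.

## Methylation calling

The pileup interrogates only the bisulfite strand a fragment derives
from: plus-strand fragments report on reference Cs, minus-strand fragments
on reference Gs (minus-strand Cs). Read bases other than C or T at a
cytosine (sequencing errors, mismapped bases) are excluded from both
counts rather than counted as unconverted — counting them as rT would
deflate rates at noisy sites. Where the two mates of one fragment overlap,
overlapped positions are counted once, from read 1.

Rates: per-site MR is S = rC/(rC+rT), undefined (NaN) without coverage;
regional "overall" MR pools raw counts, S = ΣrC/(ΣrC+ΣrT), which weights
sites by coverage and is exactly the rate of the summed counts — never the
mean of per-site rates. Except in strand-bias analyses the two cytosines
of a CG are combined into one site. CG density is the number of CG
dinucleotides within a 600-bp window centred on the focal CG, inclusive
of the focal site; windows truncated by chromosome ends are counted
as-is. The ±1 convention (including self) does not move the
density-threshold phenomena analysed here but is pinned by tests.

Context labels are non-exclusive flags from the reference: one primary
context (CG, CHG, CHH with H ∈ {A,C,T}) plus CWG (C[A/T]G), GC (preceded
by G), and GWC (G[A/T]C) where applicable.

## Strand statistics

BI = (Sn − Sp)/(Sn + Sp) ∈ [−1, 1]; a site with Sn = Sp = 0 is defined as
unbiased (BI = 0) rather than undefined. |BI| = 1 exactly when one strand
alone is methylated. The sense/antisense Pearson correlation uses sites
with ≥ 10 reads on *each* strand (configurable) and is reported missing
when fewer than two sites pass or a strand is degenerate. The BI histogram
uses bin width 0.05 over [−1, 1]. Note that the correlation measures
agreement of between-site variation: a methylome in which every site has
the same true level shows PCC ≈ 0 at finite coverage even under perfectly
symmetric maintenance, so symmetric-mode test genomes mix methylated
background with unmethylated CpG islands.

## Deletion index and RRMRs

Di = (Swt − Sko)/Swt, the fraction of WT methylation lost in the
knockout; undefined when Swt = 0 (treated as non-qualifying). An RRMR is
a maximal run of consecutive CG sites, each with Di strictly below 0.3,
of length ≥ 7 when scanning the DNMT3a/3b double knockout and ≥ 5 for the
DNMT1 single knockout (both configurable; the run-length inequality is
implemented as ≥). "Consecutive" means consecutive among sites covered in
both genotypes above the coverage floor (default combined coverage > 6,
i.e. ≥ 7): uncovered or under-covered sites are transparent, not
run-breakers, since coverage gaps would otherwise shred runs arbitrarily.
Regions span the first to last CG of the run (end = last C + 2) and carry
pooled per-genotype methylation.

RRMRs are assigned to the nearest repeat within a gap tolerance (50 bp
for DKO scans, 200 bp for 1KO; overlap counts as distance 0), ties going
to the larger overlap and then to coordinate order. Enrichment per repeat
class/family/subtype uses a two-sided Fisher exact test on assigned-RRMR
counts against the count composition of the repeat annotation
(base-pair weighting was considered and rejected as the default because
the annotation's composition summaries are count-based). The LTR-subtype
table bins element-level rates into six ranges [0, 0.1), [0.1, 0.2), …,
[0.4, 0.5), [0.5, 1] — the top range closed so a fully methylated element
is counted — keeps subtypes with more than 50 members, and orders rows by
the fraction in the top range, then the next.

## Element profiles

LINE analyses use elements with length > 1500, CG count > 30 and summed
site coverage > 50 in every genotype compared, restricted to the promoter
(100 bp upstream to 1000 bp downstream of the TSS, strand-aware; a
downstream-quarter rule is available for repeat overlap). LTRs require CG
count > 9 and coverage > 50 and use the full element; "CG density" in
this filter is interpreted as the element's CG count (the two usages are
interchangeable in the source material; the windowed quantity is exposed
separately). Body profiles bin genes/LINEs/LTRs into 50/20/15 equal-CG
bins (filters: CG > 50/20/15, length > 3000/1000/300), remainder sites to
the earliest bins, bin 1 at the element's 5' end. Elements group into CG
count deciles, or coverage tertiles (equal-count by summed coverage,
lowest first — the tertile choice is this package's reading of "three
coverage groups"). Cell values pool counts across member-element bins of
the same ordinal. Gene-promoter matrices cover TSS ± 4 kb in 40
equal-length 200-bp strand-aware bins, genes sorted by FPKM then promoter
CG count (descending) into equal-count groups.

## Expression integration

Fold change is log2(TKO/WT): positive means induced upon loss of
methylation. (The alternative WT/TKO direction is a flag; the default
follows the observation that silenced, methylated promoters are induced
in the unmethylated knockout.) The filter cascade — both FPKM > 0, FPKM
sum > 1, fold change within [−6, 6] — is applied in order with
per-criterion removal counts. Deregulation cuts are strict at ±2.5.
Subgroup analysis sorts filtered genes by fold change (or WT FPKM), cuts
them into 500 equal-count groups, and reports median fold change, pooled
methylation of all CG sites within TSS ± 500 bp, CG counts, the median
promoter CG density (600-bp window at the TSS), and median FPKM. This
module's promoter (±500 bp) is deliberately distinct from the ±4 kb
profiling window.

## The synthetic study generator

The generator emulates the study conditions, not mouse biology. Toy
genomes are iid sequence at a configurable GC fraction in which every
spontaneous CG is destroyed and CG dinucleotides are planted at exactly
the target density — 24 per 600 bp for "low" (methylation-prone) regions,
60 for "high" (island-like) ones, `600·(GC/2)²` for background — so
realized densities are controlled to within sampling of window positions.
Features (genes, LINEs, LTRs) are placed non-overlapping; genes may carry
an upstream pad synthesized with the gene's density class so TSS-centred
windows sample homogeneous sequence.

Methylation probabilities are assigned per region class. Default genotype
profiles: WT — 0.78 background, ~0 at islands, 0.85 at retroelements;
1KO (DNMT1 knockout) — 0.18 background with LINE promoters held at 0.78
and residual CHH (0.02); DKO (DNMT3a/3b knockout) — 0.18 background with
LTRs held at 0.78, no CHH; TKO ≤ 0.01 everywhere (enforced). These levels
put feature deletion indexes near 0.08 and background near 0.77, cleanly
separated by the 0.3 threshold. Under symmetric mode both strands of a CG
share one probability (taken from the plus-strand C's region, so
boundaries never split a dinucleotide); under independent mode each
strand independently adopts a high (0.9) or low (0.02) level with the
class probability as mixing weight — the expected inter-strand
correlation is then 0 within a class, and test scenarios use a single
class. The true inter-strand correlation of real strand-independent
maintenance is unknown; zero is the modelling choice here.

Libraries draw fragments uniformly with lengths uniform on [300, 600] bp
(the size-selection window governs the library; the pre-selection shear
distribution is not modelled separately). `depth` is target per-base read
coverage; each fragment yields one read pair (default 80 bp, Q40,
sequencing errors off by default). PCR bias is specified per fragment —
a copy-number map or callable, not learned from sequence — because the
phenomenon being corrected is fully characterized by the amplification
factor. The truth table records each fragment's coordinates, copy number,
and the post-conversion C/T state of every cytosine, enabling
perfect-alignment pileups (`truth_pileup`, at clone or tag level) and a
fast binomial shortcut (`sample_counts`) that emulates pileup after
perfect alignment when the aligner itself is not under test.

Expression simulation deregulates exactly the genes with methylated
(≥ 0.5) low-density (< 30) WT promoters: |log2 FC| drawn from
[2.7, 5.5] (within the ±6 filter), 85 % induced and 15 % repressed to
produce the hypermethylated down-regulated tail; all other genes draw
fold changes within ±0.45. FPKMs are lognormal and strictly positive.

What passing tests show — and what they do not: the generator's iid
sequence has no repeat families with internal divergence, no indels, no
base-quality variation, and conversion failures are position-independent;
recovery of its parameters therefore validates the statistics and the
bookkeeping (coordinates, strands, budgets, pooling), not robustness to
real-data artifacts such as mapping bias at divergent repeats or
incomplete-conversion hotspots.

## Problem sizes and numerics

Test and demonstration scenarios use 10–170 kb toy genomes at ~30×
(aligner scenarios at ~3×: 1000 pairs), and a ~10 Mb promoter-only genome
of 5200 genes for the expression analysis — sizes chosen so every oracle
comparison (full-scan alignment, exhaustive run enumeration,
hypergeometric enumeration) is itself exact and fast. Stochastic
recoveries are asserted within 3 binomial standard errors of the assigned
probability (plus the small conversion-failure offset where applicable).
All randomness flows through explicit integer seeds; reruns are
bit-identical. Degenerate inputs are defined, not errors: empty pileups
and empty site sets yield empty tables, zero-coverage rates and
zero-variance correlations are NaN with a warning, zero-margin
contingency tables give p = 1 with a warning.

## Known limitations

No gapped alignment, no variant-aware calling (a C/T SNP is
indistinguishable from conversion), no UMI or optical-duplicate handling,
no conversion-efficiency estimation from spike-ins, no general DMR
testing (the RRMR scan is a thresholded run test, not a smoothed
hypothesis test), and no RNA-seq quantification (FPKM tables are consumed
as given).
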