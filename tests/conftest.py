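import numpy as np
import pandas as pd
import pytest

from acemethylome import synthetic_data as sd
from acemethylome._seq import cg_start_positions


def random_dna(n: int, seed: int, gc: float = 0.42) -> str:
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


@pytest.fixture(scope="session")
def toy_genome():
    """Small genome with one LINE, one LTR, and one CpG island."""
    spec = sd.ToyGenomeSpec(
        chrom_length=50_000,
        feature_layout=[
            sd.FeatureSpec("LINE", length=6000),
            sd.FeatureSpec("LTR", length=500, cg_density_class="high"),
        ],
        cg_island_spec=[(1000, 60.0)],
    )
    return sd.generate_toy_genome(spec, seed=7)


@pytest.fixture(scope="session")
def repeat_genome():
    """50 kb genome in which a 2 kb segment occurs at five loci."""
    seq = list(random_dna(50_000, seed=21))
    unit = seq[4000:6000]
    for start in (9000, 15_000, 22_000, 31_000):
        seq[start:start + 2000] = unit
    return {"chr1": "".join(seq)}


def bare_genome(sequences: dict) -> sd.ToyGenome:
    """Wrap raw sequences as a ToyGenome with empty annotation tables."""
    return sd.ToyGenome(
        sequences,
        pd.DataFrame(columns=["chrom", "start", "end", "name", "score",
                              "strand", "family", "class", "cg_class"]),
        pd.DataFrame(columns=["chrom", "start", "end", "name", "score",
                              "strand", "cg_class", "promoter_pad"]),
        pd.DataFrame(columns=["chrom", "start", "end", "target_density"]),
    )


def make_cg_sites(positions, mr, cov=20, chrom="chr1"):
    """Combined-strand CG site frame with the requested per-site MR."""
    positions = np.asarray(positions)
    mr = np.broadcast_to(np.asarray(mr, dtype=float), positions.shape)
    half = cov // 2
    r_c_p = np.round(mr * half).astype(int)
    r_c_n = np.round(mr * (cov - half)).astype(int)
    df = pd.DataFrame({
        "chrom": chrom,
        "pos": positions,
        "rC_p": r_c_p,
        "rT_p": half - r_c_p,
        "rC_n": r_c_n,
        "rT_n": (cov - half) - r_c_n,
    })
    df["cov_p"] = df.rC_p + df.rT_p
    df["cov_n"] = df.rC_n + df.rT_n
    df["coverage"] = df.cov_p + df.cov_n
    df["Sp"] = df.rC_p / df.cov_p
    df["Sn"] = df.rC_n / df.cov_n
    df["S_combined"] = (df.rC_p + df.rC_n) / df.coverage
    return df


def fig_s26_scenario(seed=11):
    """The three-fragment PCR-bias scenario around one CG site.

    Three sonication fragments from different cells cover a single CG
    site; fragments 1 and 2 are methylated there, fragment 3 is not.  PCR
    amplifies them 10, 10, and 50 times on the top strand; the bottom
    strand is amplified evenly.  Returns (genome, focal position, reads).
    """
    genome = sd.generate_toy_genome(sd.ToyGenomeSpec(chrom_length=10_000), seed)
    seq = genome.sequences["chr1"]
    cgs = cg_start_positions(seq)
    p = int(cgs[np.searchsorted(cgs, 5000)])
    frags = [
        sd.Fragment("chr1", p - 10, p + 390, "+", copies=10, meth={p: True}),
        sd.Fragment("chr1", p - 20, p + 400, "+", copies=10, meth={p: True}),
        sd.Fragment("chr1", p - 30, p + 370, "+", copies=50, meth={p: False}),
        sd.Fragment("chr1", p - 15, p + 385, "-", copies=1, meth={p + 1: True}),
        sd.Fragment("chr1", p - 25, p + 395, "-", copies=1, meth={p + 1: True}),
        sd.Fragment("chr1", p - 35, p + 375, "-", copies=1, meth={p + 1: False}),
    ]
    profile = sd.MethylomeProfile("TKO", {"background": 0.0})
    probs = sd.assign_methylome(genome, profile, seed)
    lib = sd.LibraryParams(seed=seed, conversion_rate=1.0)
    sim = sd.simulate_bsseq_reads(genome, probs, lib, fragments=frags)
    return genome, p, sim
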