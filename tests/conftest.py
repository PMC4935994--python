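import numpy as np
import pytest

BASES = "ACGT"


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(BASES), n))


def mutate(seq: str, n_subs: int, rng) -> str:
    """Plant exactly n substitutions at distinct positions."""
    s = list(seq)
    for p in rng.choice(len(s), n_subs, replace=False):
        s[p] = BASES[(BASES.index(s[p]) + 1 + int(rng.integers(3))) % 4]
    return "".join(s)


@pytest.fixture(scope="session")
def mining_scenario():
    """1-Mb genome with an abundant (1%) and a rare (0.02%) family, a
    50k-pair read pool, the converged mining run and a single-run control.

    Session-scoped: the discovery loop is the most expensive computation
    in the suite and several tests interrogate the same run.
    """
    from satkit.simdata import FamilySpec, simulate_genome, simulate_reads
    from satkit.mining import satminer_loop

    rng = np.random.default_rng(99)
    mono_abundant = random_seq(rng, 193)
    mono_rare = random_seq(rng, 20)
    specs = [
        FamilySpec("abundant", mono_abundant, 1.0, layout="clustered",
                   n_loci=3, per_copy_divergence=0.02),
        FamilySpec("rare", mono_rare, 0.02, layout="clustered",
                   n_loci=1, per_copy_divergence=0.01),
    ]
    genome, truth = simulate_genome(specs, 1_000_000, seed=11)
    pairs = simulate_reads(genome, 80_000, seed=12)
    state = satminer_loop(pairs, [4000, 70000, 70000], seed=7)
    single = satminer_loop(pairs, [4000], seed=7)
    return {
        "monomers": {"abundant": mono_abundant, "rare": mono_rare},
        "truth": truth,
        "pairs": pairs,
        "state": state,
        "single": single,
    }


@pytest.fixture(scope="session")
def quant_scenario():
    """1-Mb genome with families at 5%, 1% and 0.1%, quantified from
    200k simulated read pairs against the planted monomer library."""
    from satkit.simdata import FamilySpec, simulate_genome, simulate_reads
    from satkit.quantify import (align_reads_to_library, build_library,
                                 family_abundance)

    rng = np.random.default_rng(2024)
    monomers = {"f5": random_seq(rng, 180), "f1": random_seq(rng, 150),
                "f01": random_seq(rng, 120)}
    specs = [
        FamilySpec("f5", monomers["f5"], 5.0, layout="clustered",
                   n_loci=5, per_copy_divergence=0.05),
        FamilySpec("f1", monomers["f1"], 1.0, layout="clustered",
                   n_loci=3, per_copy_divergence=0.02),
        FamilySpec("f01", monomers["f01"], 0.1, layout="clustered",
                   n_loci=2, per_copy_divergence=0.01),
    ]
    genome, truth = simulate_genome(specs, 1_000_000, seed=21)
    pairs = simulate_reads(genome, 200_000, seed=22, error_rate=0.005)
    reads = {}
    for p in pairs:
        reads[f"{p.id}/1"] = p.seq1
        reads[f"{p.id}/2"] = p.seq2
    total_nt = sum(len(s) for s in reads.values())
    library = build_library(list(monomers.items()))
    hits = align_reads_to_library(reads, library)
    quants = {q.family: q for q in family_abundance(hits, total_nt, library)}
    return {"monomers": monomers, "truth": truth, "quants": quants,
            "total_nt": total_nt}
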