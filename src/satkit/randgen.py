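"""Dinucleotide-preserving sequence shuffling and chance-occurrence scoring.

The shuffle is the Euler-path construction (Altschul-Erickson): a
sequence is a walk on the 4-vertex graph whose edges are its
dinucleotides, so any other Eulerian walk with the same start and end is
a shuffle conserving all 16 dinucleotide counts exactly. Applied to
assembly contigs it yields null genomes in which any aligned satellite
content is attributable to composition alone, which is how the chance
occurrence of short monomers is scored.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

BASES = "ACGT"


@dataclass
class ShuffleResult:
    seq: str
    seed: int
    dinucleotide_counts: dict


def dinucleotide_counts(seq: str) -> dict:
    """All 16 dinucleotide counts of a sequence (ACGT only)."""
    counts = {a + b: 0 for a in BASES for b in BASES}
    for i in range(len(seq) - 1):
        pair = seq[i:i + 2]
        if pair in counts:
            counts[pair] += 1
    return counts


def _euler_shuffle(seq: str, rng) -> str:
    """Random Eulerian rearrangement with the same start/end vertex."""
    if len(seq) < 3:
        return seq
    start, end = seq[0], seq[-1]
    # adjacency: for each vertex the multiset of next-vertices
    adj = {b: [] for b in BASES}
    for i in range(len(seq) - 1):
        adj[seq[i]].append(seq[i + 1])

    present = [b for b in BASES if adj[b] or b == end]
    while True:
        # pick a random candidate "last edge" for every vertex except `end`
        last = {}
        ok = True
        for v in present:
            if v == end:
                continue
            if not adj[v]:
                ok = False
                break
            last[v] = adj[v][rng.integers(0, len(adj[v]))]
        if not ok:  # pragma: no cover - malformed walk
            raise ValueError("sequence is not a valid walk")
        # the chosen last edges must form an arborescence into `end`
        good = True
        for v in last:
            u, steps = v, 0
            while u != end:
                if u not in last or steps > 4:
                    good = False
                    break
                u = last[u]
                steps += 1
            if not good:
                break
        if good:
            break

    # shuffle the remaining edges, append the designated last edge
    lists = {}
    for v in present:
        edges = list(adj[v])
        if v in last:
            edges.remove(last[v])
        perm = rng.permutation(len(edges)) if edges else []
        edges = [edges[i] for i in perm]
        if v in last:
            edges.append(last[v])
        lists[v] = edges

    out = [start]
    ptr = {v: 0 for v in lists}
    v = start
    total = len(seq) - 1
    for _ in range(total):
        nxt = lists[v][ptr[v]]
        ptr[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def dinucleotide_shuffle(seq: str, seed: int) -> ShuffleResult:
    """Shuffle preserving all 16 dinucleotide counts exactly.

    Deterministic per seed; length, mononucleotide counts and the first
    and last base are conserved as well. Runs of N split the sequence and
    each N-free segment is shuffled independently.
    """
    if len(seq) < 2:
        raise ValueError("sequence must be at least 2 bases long")
    if set(seq) - set(BASES + "N"):
        raise ValueError("alphabet restricted to ACGT (N allowed as separator)")
    rng = np.random.default_rng(seed)
    if "N" in seq:
        parts = []
        for is_n, grp in itertools.groupby(seq, key=lambda c: c == "N"):
            chunk = "".join(grp)
            parts.append(chunk if is_n else _euler_shuffle(chunk, rng))
        shuffled = "".join(parts)
    else:
        shuffled = _euler_shuffle(seq, rng)
    return ShuffleResult(shuffled, seed, dinucleotide_counts(shuffled))


def random_occurrence(library, genome: dict, n_replicates: int, seed: int,
                      min_aligned: int = 200):
    """Chance satellite content in dinucleotide-preserving null genomes.

    Each replicate shuffles every contig independently and scans the
    shuffled assembly against the library. Returns (per-replicate
    DataFrame, per-family summary with mean and sd of the contig counts
    and aligned nucleotides across replicates).
    """
    import pandas as pd
    from .quantify import scan_assembly
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not genome:
        raise ValueError("empty genome")
    records = []
    for rep in range(n_replicates):
        shuffled = {name: dinucleotide_shuffle(s, seed + 7919 * rep + i).seq
                    for i, (name, s) in enumerate(genome.items())}
        _stats, summary = scan_assembly(shuffled, library, min_aligned=min_aligned)
        for _idx, row in summary.iterrows():
            records.append({"replicate": rep, "family": row["family"],
                            "n_contigs": row["n_contigs"],
                            "aligned_nt": row["total_aligned_nt"]})
    table = pd.DataFrame(records)
    summary = table.groupby("family").agg(
        mean_contigs=("n_contigs", "mean"), sd_contigs=("n_contigs", "std"),
        mean_aligned_nt=("aligned_nt", "mean"),
        sd_aligned_nt=("aligned_nt", "std")).reset_index()
    return table, summary
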