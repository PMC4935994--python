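"""Synthetic satellitome genomes and paired-end reads with known ground truth.

The generator embodies the array-size model of satellite-DNA organisation:
a family is present either as a few large (FISH-visible, >= 1.5 kb) arrays
("clustered"), as many short (< 1.5 kb) arrays scattered across the genome
("scattered"), or both ("mixed"). Each planted monomer copy is mutated
independently at a per-copy substitution rate, so read-vs-consensus
divergence and the resulting repeat landscape have a known expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._align import revcomp
from .seqio import ReadPair

BASES = "ACGT"
CLUSTER_THRESHOLD_BP = 1500  # FISH visibility scale separating array classes


@dataclass
class FamilySpec:
    """Ground-truth description of one satellite family to plant."""

    name: str
    monomer: str
    genome_proportion: float  # target % of the genome
    layout: str = "clustered"  # clustered | scattered | mixed
    n_loci: int | None = None
    per_copy_divergence: float = 0.02  # substitutions per site per copy
    array_sizes: Sequence[int] | None = None  # explicit per-locus sizes (bp)
    indel_rate: float = 0.0  # per-site indel rate per copy (off by default)

    def __post_init__(self):
        if not 0 < self.genome_proportion <= 50:
            raise ValueError("genome_proportion must be in (0, 50] percent")
        if not 0 <= self.per_copy_divergence <= 0.3:
            raise ValueError("per_copy_divergence must be in [0, 0.3]")
        if self.layout not in ("clustered", "scattered", "mixed"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if set(self.monomer) - set(BASES):
            raise ValueError("monomer must be ACGT only")


@dataclass
class PlantedLocus:
    family: str
    contig: str
    start: int
    end: int
    n_copies: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthTable:
    """Exact accounting of what was planted where."""

    loci: list = field(default_factory=list)
    genome_size: int = 0
    realized_proportion: dict = field(default_factory=dict)
    realized_divergence: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [{"family": l.family, "contig": l.contig, "start": l.start,
              "end": l.end, "n_copies": l.n_copies} for l in self.loci])


def _mutate_copy(monomer: str, rate: float, indel_rate: float, rng) -> tuple[str, int]:
    """One monomer copy with independent substitutions; returns (seq, n_subs)."""
    seq = list(monomer)
    n_sub = rng.binomial(len(seq), rate) if rate > 0 else 0
    if n_sub:
        for pos in rng.choice(len(seq), size=n_sub, replace=False):
            cur = seq[pos]
            seq[pos] = BASES[(BASES.index(cur) + rng.integers(1, 4)) % 4]
    if indel_rate > 0:
        n_id = rng.binomial(len(seq), indel_rate)
        for _ in range(n_id):
            pos = int(rng.integers(0, len(seq)))
            if rng.random() < 0.5 and len(seq) > 1:
                del seq[pos]
            else:
                seq.insert(pos, BASES[rng.integers(0, 4)])
    return "".join(seq), int(n_sub)


def _locus_sizes(spec: FamilySpec, total_nt: int, rng) -> list[int]:
    if spec.array_sizes is not None:
        return list(spec.array_sizes)
    L = len(spec.monomer)
    if spec.layout == "clustered":
        n = spec.n_loci or max(1, round(total_nt / 4000))
    elif spec.layout == "scattered":
        n = spec.n_loci or max(2, math.ceil(total_nt / 600))
    else:  # mixed: one large cluster plus scattered remainder
        big = max(CLUSTER_THRESHOLD_BP, total_nt // 2)
        rest = total_nt - big
        sizes = [big]
        if rest > 2 * L:
            sizes += _locus_sizes(
                FamilySpec(spec.name, spec.monomer, spec.genome_proportion,
                           layout="scattered", n_loci=spec.n_loci),
                rest, rng)
        return sizes
    base = total_nt // n
    if spec.layout == "scattered" and base >= CLUSTER_THRESHOLD_BP:
        n = math.ceil(total_nt / (CLUSTER_THRESHOLD_BP - L))
        base = total_nt // n
    return [base] * n


def random_background(size: int, rng, dinucleotide_freqs: dict | None = None) -> str:
    """Random background sequence; optionally a first-order Markov chain
    matching the given dinucleotide frequencies."""
    if dinucleotide_freqs is None:
        return "".join(np.array(list(BASES))[rng.integers(0, 4, size=size)])
    # conditional next-base distributions from the 16 dinucleotide frequencies
    cond = {}
    for a in BASES:
        w = np.array([dinucleotide_freqs.get(a + b, 0.0) for b in BASES], float)
        cond[a] = w / w.sum() if w.sum() > 0 else np.full(4, 0.25)
    out = [BASES[rng.integers(0, 4)]]
    u = rng.random(size - 1)
    for i in range(size - 1):
        cum = np.cumsum(cond[out[-1]])
        out.append(BASES[int(np.searchsorted(cum, u[i]))])
    return "".join(out)


def simulate_genome(specs: Sequence[FamilySpec], genome_size: int, seed: int,
                    dinucleotide_freqs: dict | None = None,
                    n_contigs: int = 1) -> tuple[dict, TruthTable]:
    """Plant satellite arrays into a random background genome.

    Arrays overwrite background sequence (genome size is exact); loci are
    non-overlapping with a small margin. Returns the genome as an ordered
    ``{contig: sequence}`` mapping plus a :class:`TruthTable` whose realized
    proportions come from exact accounting of the planted intervals.
    """
    if sum(s.genome_proportion for s in specs) >= 50:
        raise ValueError("total target proportion must stay below 50%")
    rng = np.random.default_rng(seed)
    contig_sizes = [genome_size // n_contigs] * n_contigs
    contig_sizes[-1] += genome_size - sum(contig_sizes)
    names = [f"contig{i + 1}" for i in range(n_contigs)]
    contigs = {n: list(random_background(s, rng, dinucleotide_freqs))
               for n, s in zip(names, contig_sizes)}

    truth = TruthTable(genome_size=genome_size)
    occupied = {n: [] for n in names}  # placed (start, end) per contig
    margin = 150

    for spec in specs:
        total_nt = int(round(spec.genome_proportion / 100 * genome_size))
        L = len(spec.monomer)
        if total_nt < 2 * L:
            raise ValueError(
                f"{spec.name}: target proportion too small for two monomer copies")
        sizes = _locus_sizes(spec, total_nt, rng)
        # convert byte targets to whole copy counts that sum to the family
        # total, so the realized proportion tracks the target closely
        copy_counts = [max(2, round(s / L)) for s in sizes]
        target_copies = max(2 * len(sizes), round(total_nt / L))
        copy_counts[-1] = max(2, copy_counts[-1] + target_copies - sum(copy_counts))
        subs = copied = 0
        for copies in copy_counts:
            parts = []
            for _ in range(copies):
                copy, n_sub = _mutate_copy(spec.monomer, spec.per_copy_divergence,
                                           spec.indel_rate, rng)
                parts.append(copy)
                subs += n_sub
                copied += L
            array = "".join(parts)
            placed = False
            for _attempt in range(1000):
                ci = int(rng.integers(0, n_contigs))
                name = names[ci]
                limit = contig_sizes[ci] - len(array) - margin
                if limit <= margin:
                    continue
                start = int(rng.integers(margin, limit))
                end = start + len(array)
                if all(end + margin <= s or start >= e + margin
                       for s, e in occupied[name]):
                    contigs[name][start:end] = array
                    occupied[name].append((start, end))
                    truth.loci.append(PlantedLocus(spec.name, name, start, end, copies))
                    placed = True
                    break
            if not placed:
                raise ValueError(f"could not place a {len(array)} bp array "
                                 f"of {spec.name}; genome too crowded")
        fam_nt = sum(l.length for l in truth.loci if l.family == spec.name)
        truth.realized_proportion[spec.name] = 100.0 * fam_nt / genome_size
        truth.realized_divergence[spec.name] = subs / copied if copied else 0.0

    return {n: "".join(c) for n, c in contigs.items()}, truth


def simulate_reads(genome: dict, n_pairs: int, seed: int, read_len: int = 101,
                   insert_mean: float = 226.0, insert_sd: float = 81.0,
                   error_rate: float = 0.005) -> list:
    """Paired-end reads by uniform fragment sampling from both strands.

    Insert sizes are truncated-normal with a floor at ``read_len``;
    substitution errors are planted at ``error_rate`` per base and the
    constant Phred quality is consistent with that rate.
    """
    if read_len > min(len(s) for s in genome.values()):
        raise ValueError("read_len exceeds the shortest contig")
    names = list(genome)
    lengths = np.array([len(genome[n]) for n in names], float)
    if read_len > insert_mean:
        raise ValueError("read_len must not exceed insert_mean")
    rng = np.random.default_rng(seed)
    weights = lengths / lengths.sum()
    q = 40 if error_rate <= 0 else min(40, int(round(-10 * math.log10(error_rate))))
    quals = tuple([q] * read_len)

    contig_idx = rng.choice(len(names), size=n_pairs, p=weights)
    inserts = np.clip(rng.normal(insert_mean, insert_sd, size=n_pairs),
                      read_len, None).astype(int)
    flip = rng.random(n_pairs) < 0.5
    u = rng.random(n_pairs)

    pairs = []
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    for i in range(n_pairs):
        name = names[contig_idx[i]]
        seq = genome[name]
        ins = min(int(inserts[i]), len(seq))
        start = int(u[i] * (len(seq) - ins + 1))
        frag = seq[start:start + ins]
        if flip[i]:
            frag = revcomp(frag)
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])
        if error_rate > 0:
            r1 = _add_errors(r1, error_rate, rng, base_arr)
            r2 = _add_errors(r2, error_rate, rng, base_arr)
        pairs.append(ReadPair(f"sim{i}", r1, r2, quals, quals))
    return pairs


def _add_errors(read: str, rate: float, rng, base_arr) -> str:
    n_err = rng.binomial(len(read), rate)
    if not n_err:
        return read
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(read), size=n_err, replace=False)
    for p in pos:
        choices = base_arr[base_arr != arr[p]]
        arr[p] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()
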