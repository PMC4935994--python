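"""Abundance and divergence quantification against a satellite library.

Reads (or assembly contigs) are aligned to concatenated-monomer
references; each hit records the transition proportion P and transversion
proportion Q over its aligned columns and the resulting Kimura
2-parameter distance

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

expressed in percent. Family abundance is the summed aligned nucleotides
over all its variants, normalised by the total sampled nucleotides
(genome proportion, %); the per-family mean divergence is weighted by
aligned nucleotides, and the repeat landscape bins abundance by 1%
divergence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._align import (KmerIndex, canonical_kmers, edlib_pairs, make_local_aligner,
                     local_alignment_pairs, revcomp, stats_from_pairs)
from .mining import build_reference_dimers
from .tandem import ConsensusMonomer

MIN_HIT_LEN = 25
MIN_HIT_IDENTITY = 65.0
SATURATION_BIN = 50  # landscape bin for hits beyond the K2P domain


class K2PSaturationError(ValueError):
    """P/Q combination outside the Kimura 2-parameter domain."""


def k2p_divergence(P: float, Q: float) -> float:
    """Kimura 2-parameter distance, in percent.

    ``P`` and ``Q`` are the proportions of aligned columns showing
    transitions and transversions respectively. Raises
    :class:`K2PSaturationError` when 1-2P-Q <= 0 or 1-2Q <= 0.
    """
    if P < 0 or Q < 0 or P + Q > 1:
        raise ValueError("P and Q must be non-negative with P + Q <= 1")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise K2PSaturationError(f"saturated: P={P}, Q={Q}")
    return -50.0 * math.log(w1 * math.sqrt(w2)) + 0.0  # normalise -0.0


@dataclass
class LibraryReference:
    """One alignment reference: a variant's concatenated-monomer sequence."""

    variant: str       # "<family>#<variant index>"
    family: str
    monomer_length: int
    seq: str


@dataclass
class LibraryHit:
    query_id: str
    variant: str
    family: str
    q_start: int   # 0-based half-open on the query
    q_end: int
    strand: str
    aligned_nt: int
    P: float
    Q: float
    k2p: float     # percent; nan when saturated
    saturated: bool = False
    score: float = 0.0


@dataclass
class FamilyQuant:
    family: str
    abundance: float                 # % of sampled nucleotides
    mean_divergence: float           # abundance-weighted K2P %, nan if no hits
    landscape: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass
class ContigRepeatStat:
    contig_id: str
    family: str
    aligned_nt: int
    n_repeats: float


def build_library(families, min_len: int = 200) -> list:
    """Alignment references from a catalog of :class:`~satkit.catalog.SatFamily`
    (or plain (name, monomer) pairs)."""
    refs = []
    for fam in families:
        if hasattr(fam, "variants"):  # SatFamily
            name = fam.name or f"family{fam.catalog_number}"
            for v in fam.variants:
                dimer = build_reference_dimers([v.seq], min_len)[0]
                refs.append(LibraryReference(f"{name}#{v.variant_index}", name,
                                             len(v.seq), dimer))
        else:
            name, mono = fam
            if isinstance(mono, ConsensusMonomer):
                mono = mono.seq
            dimer = build_reference_dimers([mono], min_len)[0]
            refs.append(LibraryReference(f"{name}#1", name, len(mono), dimer))
    if not refs:
        raise ValueError("empty library")
    return refs


def _hit_from_pairs(query_id, ref, pairs, q_start, q_end, strand, qlen, score):
    st = stats_from_pairs(pairs)
    aligned = st.matches + st.substitutions  # gap columns excluded
    if aligned == 0:
        return None
    P = st.transitions / aligned
    Q = st.transversions / aligned
    try:
        k2p = k2p_divergence(P, Q)
        saturated = False
    except K2PSaturationError:
        k2p = float("nan")
        saturated = True
    if strand == "-":
        q_start, q_end = qlen - q_end, qlen - q_start
    return LibraryHit(query_id, ref.variant, ref.family, q_start, q_end, strand,
                      aligned, P, Q, k2p, saturated, score)


_READ_ALIGNER = make_local_aligner(match=1.0, mismatch=-1.0,
                                   gap_open=-3.0, gap_extend=-2.0)


def align_reads_to_library(reads, library, min_hit_len: int = MIN_HIT_LEN,
                           min_identity: float = MIN_HIT_IDENTITY,
                           k: int = 13) -> list:
    """Local-align reads against the library; best non-overlapping hits.

    ``reads`` is an iterable of (id, sequence) or a mapping. Candidate
    read/reference pairs come from shared canonical k-mers; candidates are
    Smith-Waterman aligned on both strands, and per read the best-scoring
    hits are kept greedily, discarding hits overlapping an accepted one by
    more than half their length.
    """
    if not library:
        raise ValueError("empty library")
    index = KmerIndex(k=k)
    for i, ref in enumerate(library):
        index.add(i, ref.seq)
    items = reads.items() if isinstance(reads, dict) else reads
    hits = []
    for rid, seq in items:
        cands = index.candidates(seq)
        if not cands:
            continue
        read_hits = []
        for ci in cands:
            ref = library[ci]
            for strand, query in (("+", seq), ("-", revcomp(seq))):
                res = local_alignment_pairs(_READ_ALIGNER, query, ref.seq)
                if res is None:
                    continue
                pairs, qs, qe, _ts, score = res
                hit = _hit_from_pairs(rid, ref, pairs, qs, qe, strand,
                                      len(seq), score)
                if hit and hit.aligned_nt >= min_hit_len and \
                        100.0 * (1.0 - hit.P - hit.Q) >= min_identity:
                    read_hits.append(hit)
        read_hits.sort(key=lambda h: (-h.score, h.variant))
        accepted = []
        for h in read_hits:
            length = h.q_end - h.q_start
            clash = False
            for a in accepted:
                ov = min(h.q_end, a.q_end) - max(h.q_start, a.q_start)
                if ov > 0.5 * min(length, a.q_end - a.q_start):
                    clash = True
                    break
            if not clash:
                accepted.append(h)
        hits.extend(accepted)
    return hits


def family_abundance(hits, total_sampled_nt: int, library=None) -> list:
    """Per-family genome proportion and weighted mean divergence.

    Landscape vectors are attached (1% K2P bins, saturated hits in the
    overflow bin) and their sums reproduce the abundances exactly.
    """
    if total_sampled_nt <= 0:
        raise ValueError("total_sampled_nt must be positive")
    families = {}
    if library:
        for ref in library:
            families.setdefault(ref.family, [])
    for h in hits:
        families.setdefault(h.family, []).append(h)
    out = []
    for fam in sorted(families):
        fam_hits = families[fam]
        nt = sum(h.aligned_nt for h in fam_hits)
        abundance = 100.0 * nt / total_sampled_nt
        good = [h for h in fam_hits if not h.saturated]
        good_nt = sum(h.aligned_nt for h in good)
        mean_div = (sum(h.aligned_nt * h.k2p for h in good) / good_nt
                    if good_nt else float("nan"))
        landscape = np.zeros(SATURATION_BIN + 1)
        for h in fam_hits:
            b = SATURATION_BIN if h.saturated else min(int(h.k2p), SATURATION_BIN)
            landscape[b] += 100.0 * h.aligned_nt / total_sampled_nt
        out.append(FamilyQuant(fam, abundance, mean_div, landscape))
    return out


def repeat_landscape(hits, total_sampled_nt: int) -> dict:
    """Family -> abundance per 1% divergence bin [0,1), [1,2), ..."""
    return {fq.family: fq.landscape
            for fq in family_abundance(hits, total_sampled_nt)}


# ---------------------------------------------------------------------------
# assembly scanning

def _seed_regions(contig: str, ref_index: dict, k: int, merge_gap: int = 60):
    """Per reference, merged intervals of the contig seeded by shared k-mers."""
    regions: dict = {}
    for kmer, pos, _fwd in canonical_kmers(contig, k):
        for ri in ref_index.get(kmer, ()):
            regions.setdefault(ri, []).append(pos)
    merged: dict = {}
    for ri, positions in regions.items():
        positions.sort()
        out = []
        start = prev = positions[0]
        for p in positions[1:]:
            if p - prev > merge_gap:
                out.append((start, prev + k))
                start = p
            prev = p
        out.append((start, prev + k))
        merged[ri] = out
    return merged


def scan_assembly(contigs: dict, library, min_aligned: int = 200,
                  min_identity: float = MIN_HIT_IDENTITY,
                  min_region: int = 20) -> tuple:
    """Repeat content of assembly contigs.

    For each (contig, family): total aligned nucleotides over all seeded
    regions verified by alignment against a tandem extension of the
    reference, and ``n_repeats`` = aligned_nt / monomer length. The
    summary counts, per family, contigs carrying at least ``min_aligned``
    aligned bp and the maximum repeat count per contig (MNRPC).
    """
    import pandas as pd
    if not contigs:
        raise ValueError("empty assembly")
    if not library:
        raise ValueError("empty library")
    # index both strands of every reference with an adaptive seed size
    ref_index: dict = {}
    ks = {}
    for i, ref in enumerate(library):
        k = max(6, min(13, ref.monomer_length))
        ks.setdefault(k, set()).add(i)
        for kmer, _pos, _fwd in canonical_kmers(ref.seq, k):
            ref_index.setdefault(kmer, set()).add(i)

    stats = []
    for cid, contig in contigs.items():
        per_family: dict = {}
        for k, ref_set in ks.items():
            merged = _seed_regions(contig, ref_index, k)
            for ri, intervals in merged.items():
                if ri not in ref_set:
                    continue
                ref = library[ri]
                for start, end in intervals:
                    # padding catches diverged edges whose k-mers are absent,
                    # but can cost an edge base to alignment ambiguity; score
                    # the bare seed interval as well and keep the better
                    aligned = 0
                    for pad in (min(ref.monomer_length, 25), 0):
                        lo = max(0, start - pad)
                        hi = min(len(contig), end + pad)
                        region = contig[lo:hi]
                        if len(region) < min_region:
                            continue
                        aligned = max(aligned,
                                      _align_region(region, ref, min_identity))
                    if aligned:
                        per_family[ref.family] = per_family.get(ref.family, 0) + aligned
        for fam, nt in per_family.items():
            mono = next(r.monomer_length for r in library if r.family == fam)
            stats.append(ContigRepeatStat(cid, fam, nt, nt / mono))

    rows = []
    seen = set()
    for ref in library:
        fam = ref.family
        if fam in seen:
            continue
        seen.add(fam)
        fam_stats = [s for s in stats if s.family == fam]
        rows.append({"family": fam,
                     "n_contigs": sum(1 for s in fam_stats
                                      if s.aligned_nt >= min_aligned),
                     "mnrpc": int(max((s.n_repeats for s in fam_stats),
                                      default=0.0)),
                     "total_aligned_nt": sum(s.aligned_nt for s in fam_stats)})
    return stats, pd.DataFrame(rows)


def _trim_to_match_runs(pairs, run: int = 8):
    """Drop alignment columns outside the first/last run of consecutive
    matches, removing flanking sequence dragged in by region padding."""
    match = [a == b and a != "-" for a, b in pairs]
    first = last = None
    streak = 0
    for i, m in enumerate(match):
        streak = streak + 1 if m else 0
        if streak >= run:
            if first is None:
                first = i - run + 1
            last = i
    if first is None:
        return []
    return pairs[first:last + 1]


def _align_region(region: str, ref: LibraryReference, min_identity: float) -> int:
    """Aligned (non-gap) nucleotides of ``region`` against a tandem
    extension of the reference monomer; 0 when below ``min_identity``.

    Identity is matches over all alignment columns (gaps included), which
    keeps heavily gapped chance alignments of unrelated sequence out.
    """
    n_copies = math.ceil(len(region) / ref.monomer_length) + 2
    monomer = ref.seq[:ref.monomer_length]
    best = 0
    for target_seed in (monomer, revcomp(monomer)):
        target = target_seed * n_copies
        pairs = _trim_to_match_runs(edlib_pairs(region, target, mode="HW"))
        if not pairs:
            continue
        st = stats_from_pairs(pairs)
        aligned = st.matches + st.substitutions
        if st.columns and 100.0 * st.matches / st.columns >= min_identity:
            best = max(best, aligned)
    return best
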