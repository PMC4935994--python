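"""Iterative satellite mining: cluster, subtract, re-cluster until convergence.

One low-coverage clustering run only reveals the most abundant tandem
repeats: a rare family contributes too few reads at the sampling depth a
single run can afford. The loop therefore alternates discovery and
subtraction: reads matching every repeat found so far (satellite
consensus dimers plus the non-tandem contigs of selected clusters, the
"custom repeat database") are filtered out of the pool, and a larger
sample of the survivors is clustered in the next round. Rare satellites
climb above the detection floor once the dominant repeats stop consuming
the sample. The loop stops when a round adds no new satellite family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ._align import KmerIndex, infix_identity, revcomp
from .clustering import build_read_graph, connected_components, \
    select_candidate_clusters
from .catalog import pairwise_identity
from .seqio import sample_pairs
from .tandem import (ConsensusMonomer, assemble_cluster, consensus_monomer,
                     detect_tandem_period, periodic_core, split_into_monomers,
                     MIN_PERIOD_CONTIG)

DEFAULT_DIMER_MIN_LEN = 200
DEFAULT_FILTER_IDENTITY = 90.0
DEFAULT_FILTER_COVERAGE = 0.9
MIN_CLUSTER_READS = 10   # below this, period/consensus calls are unreliable
NEW_FAMILY_MAX_IDENTITY = 95.0  # above: merges into the known family


@dataclass
class MiningState:
    """Evolving state of the discovery loop."""

    iteration: int = 0
    known_satellites: list = field(default_factory=list)
    known_other_repeats: list = field(default_factory=list)
    reads_per_run: int = 0
    new_found_last: int = 0
    converged: bool = False
    warning: bool = False
    history: list = field(default_factory=list)


def build_reference_dimers(families, min_len: int = DEFAULT_DIMER_MIN_LEN) -> list:
    """Concatenated-monomer references for read filtering and masking.

    At least a dimer; short monomers are concatenated until the reference
    strictly surpasses ``min_len`` bp, so reads spanning the monomer
    junction still align end-to-end.
    """
    if not families:
        raise ValueError("no monomers supplied")
    refs = []
    for fam in families:
        seq = fam.seq if isinstance(fam, ConsensusMonomer) else fam
        k = max(2, min_len // len(seq) + 1)
        refs.append(seq * k)
    return refs


def _matches_any(seq: str, index: KmerIndex, refs: dict, min_identity: float,
                 min_coverage: float) -> bool:
    cands = index.candidates(seq)
    if not cands:
        return False
    span = max(1, math.ceil(min_coverage * len(seq)))
    queries = {seq, seq[:span], seq[-span:]}
    for name in cands:
        ref = refs[name]
        for q in queries:
            for query in (q, revcomp(q)):
                if infix_identity(query, ref) >= min_identity:
                    return True
    return False


def filter_matching_reads(pairs, references, min_identity: float = DEFAULT_FILTER_IDENTITY,
                          min_coverage: float = DEFAULT_FILTER_COVERAGE,
                          k: int = 13):
    """Drop pairs in which either mate matches any reference sequence.

    A mate matches when at least ``min_coverage`` of it aligns to a
    reference infix (either strand) at ``min_identity`` percent; the test
    aligns the full mate and its leading/trailing ``min_coverage``
    fraction, so reads whose repeat content is a prefix or suffix are
    caught. Pairs with no candidate reference (no shared k-mer) pass
    untouched.
    """
    if not references:
        raise ValueError("no references supplied")
    refs = {i: r for i, r in enumerate(references)}
    index = KmerIndex(k=k)
    for name, ref in refs.items():
        index.add(name, ref)
    out = []
    for pair in pairs:
        if _matches_any(pair.seq1, index, refs, min_identity, min_coverage):
            continue
        if _matches_any(pair.seq2, index, refs, min_identity, min_coverage):
            continue
        out.append(pair)
    return out


def _deepest_window(seq: str, coverage, width: int) -> str:
    """The ``width``-bp window of the contig with the highest total coverage."""
    if len(seq) <= width:
        return seq
    best_start, best_cov = 0, -1.0
    window = float(sum(coverage[:width]))
    best_cov = window
    for s in range(1, len(seq) - width + 1):
        window += float(coverage[s + width - 1]) - float(coverage[s - 1])
        if window > best_cov:
            best_start, best_cov = s, window
    return seq[best_start:best_start + width]


def _candidate_consensi(cluster, rg, max_contigs: int = 3):
    """Consensus monomers (or raw contigs) from one candidate cluster."""
    reads = {m: rg.reads[m] for m in cluster.members}
    contigs = assemble_cluster(reads, rg.graph)
    results = []
    for contig in contigs[:max_contigs]:
        seq = contig.seq
        lead = len(seq) - len(seq.lstrip("N"))
        seq = seq.strip("N")
        coverage = contig.coverage[lead:lead + len(seq)]
        if len(seq) < MIN_PERIOD_CONTIG:
            continue
        period = detect_tandem_period(seq)
        if period is None:
            # long monomers: the contig span wraps below two periods, but
            # layout back-edges still betray the periodicity
            hint = contig.hinted_period()
            if hint is not None and hint <= len(seq):
                period = hint
        cons = None
        if period is not None:
            core = periodic_core(seq, period)
            if len(core) // period >= 2:
                monomers, _rem = split_into_monomers(core, period)
                cons = consensus_monomer(monomers)
            else:
                # layout contigs of long monomers hold < 2 full copies;
                # the deepest-coverage window is the best-supported copy
                cons = ConsensusMonomer.from_seq(
                    _deepest_window(seq, coverage, period))
        results.append((cons, seq))
    return results


def satminer_loop(pairs, schedule, seed: int, *, min_identity: float = 90.0,
                  min_overlap_frac: float = 0.55, density_threshold: float = 0.1,
                  min_cluster_reads: int = MIN_CLUSTER_READS,
                  new_family_max_identity: float = NEW_FAMILY_MAX_IDENTITY,
                  filter_identity: float = DEFAULT_FILTER_IDENTITY,
                  filter_coverage: float = DEFAULT_FILTER_COVERAGE,
                  log=None) -> MiningState:
    """Run the iterative mining protocol over a pool of read pairs.

    ``schedule`` lists the number of pairs to cluster per iteration;
    each iteration samples fresh reads from the filtered remainder of the
    pool. Terminates early once an iteration adds zero new satellites;
    if the schedule is exhausted while satellites are still being found,
    the state carries a convergence warning.
    """
    if not schedule:
        raise ValueError("empty schedule")
    pool = list(pairs)
    state = MiningState()
    for it, n_pairs in enumerate(schedule, 1):
        state.iteration = it
        refs = []
        if state.known_satellites:
            refs += build_reference_dimers(state.known_satellites)
        refs += state.known_other_repeats
        if refs and pool:
            pool = filter_matching_reads(pool, refs, filter_identity,
                                         filter_coverage)
        if not pool:
            state.new_found_last = 0
            state.converged = True
            state.history.append({"iteration": it, "reads_used": 0,
                                  "clusters_examined": 0, "new_satellites": 0})
            break
        n_take = min(n_pairs, len(pool))
        sample = sample_pairs(pool, n_take, seed + it)
        taken = {id(p) for p in sample}
        pool = [p for p in pool if id(p) not in taken]
        state.reads_per_run = n_take

        reads = {}
        for p in sample:
            reads[f"{p.id}/1"] = p.seq1
            reads[f"{p.id}/2"] = p.seq2
        rg = build_read_graph(reads, min_identity=min_identity,
                              min_overlap_frac=min_overlap_frac)
        clusters = connected_components(rg)
        candidates = [c for c in select_candidate_clusters(clusters, density_threshold)
                      if len(c) >= min_cluster_reads]
        new_found = 0
        for cluster in candidates:
            results = _candidate_consensi(cluster, rg)
            got_satellite = False
            for cons, _contig in results:
                if cons is None:
                    continue
                is_new = all(pairwise_identity(cons, known) <= new_family_max_identity
                             for known in state.known_satellites)
                if is_new:
                    state.known_satellites.append(cons)
                    new_found += 1
                got_satellite = True
                break
            if not got_satellite:
                state.known_other_repeats.extend(c for _x, c in results)
        state.new_found_last = new_found
        state.history.append({"iteration": it, "reads_used": n_take,
                              "clusters_examined": len(candidates),
                              "new_satellites": new_found})
        if log is not None:
            log.info("iteration %d: %d reads, %d candidate clusters, "
                     "%d new satellites", it, 2 * n_take, len(candidates), new_found)
        if new_found == 0:
            state.converged = True
            break
    if not state.converged:
        state.warning = True
    return state
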