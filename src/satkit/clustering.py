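"""Read-similarity graph construction and satellite-candidate cluster selection.

Reads sampled from a genome are compared all-vs-all (canonical k-mer
prefilter followed by alignment of the seeded overlap); connected
components of the resulting graph are repeat clusters. Tandem repeats
produce dense ("globular") or ring-shaped components because reads from
different monomer copies align at every phase, whereas single-copy
sequence yields sparse chains. Candidate satellite clusters are the
globular/ring components whose density (mean links per read) exceeds a
threshold, 0.1 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from zlib import crc32

import networkx as nx

from ._align import canonical_kmers, edlib_distance, make_local_aligner, \
    local_alignment_pairs, revcomp, stats_from_pairs

DEFAULT_MIN_IDENTITY = 90.0
DEFAULT_MIN_OVERLAP_FRAC = 0.55
DEFAULT_DENSITY_THRESHOLD = 0.1
PREFILTER_K = 13


@dataclass
class ReadGraph:
    """Undirected similarity graph over reads.

    Edge attributes: ``identity`` (%), ``overlap`` (aligned bp), ``offset``
    (start of the second read in the first read's forward frame) and
    ``same_strand``.
    """

    graph: nx.Graph
    reads: dict

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


@dataclass
class RepeatCluster:
    cluster_id: int
    members: list
    density: float = 0.0
    shape: str = ""
    contigs: list = field(default_factory=list)
    genome_proportion: float = 0.0

    def __len__(self):
        return len(self.members)


def _as_read_dict(reads) -> dict:
    if isinstance(reads, dict):
        return reads
    return {i: s for i, s in enumerate(reads)}


def _overlap_identity(a: str, b: str, offset: int, min_overlap: int):
    """Identity of the overlap implied by a shared seed at diagonal ``offset``.

    ``offset`` is the position of b's first base in a's coordinates. The two
    overlap substrings are aligned end-to-end with edlib, so small indels
    are tolerated.
    """
    a_start = max(0, offset)
    b_start = max(0, -offset)
    ov = min(len(a) - a_start, len(b) - b_start)
    if ov < min_overlap:
        return None
    sub_a = a[a_start:a_start + ov]
    sub_b = b[b_start:b_start + ov]
    cap = int(0.5 * ov)
    d = edlib_distance(sub_a, sub_b, k=cap)
    if d < 0:
        return None
    return 100.0 * (ov - d) / ov, ov


def _exact_edge(a: str, b: str, min_identity: float, min_overlap: int, aligner):
    """Best local alignment over both strands (reference semantics)."""
    best = None
    for same, target in ((True, b), (False, revcomp(b))):
        res = local_alignment_pairs(aligner, a, target)
        if res is None:
            continue
        pairs, q_start, _q_end, t_start, score = res
        st = stats_from_pairs(pairs)
        if st.columns >= min_overlap and st.identity >= min_identity:
            if best is None or st.identity > best[0]:
                offset = q_start - t_start  # start of b' in a's frame
                best = (st.identity, st.columns, offset, same)
    return best


def build_read_graph(reads, min_identity: float = DEFAULT_MIN_IDENTITY,
                     min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
                     k: int = PREFILTER_K, exact: bool = False,
                     kmer_sample: int | None = None) -> ReadGraph:
    """All-vs-all read comparison.

    An edge joins two reads when their best alignment (either strand)
    reaches ``min_identity`` percent over at least ``min_overlap_frac`` of
    the shorter read. By default candidate pairs come from shared canonical
    k-mers and the alignment is evaluated on the seeded diagonal;
    ``exact=True`` performs full Smith-Waterman on every pair instead
    (quadratic -- intended for small inputs and cross-checks).

    ``kmer_sample``: keep only k-mers whose (stable) hash is 0 modulo this
    value. Selection depends on the k-mer sequence alone, so two
    overlapping reads always retain the same seeds; it bounds the cost of
    enumerating candidate pairs inside deep repeat bins. Defaults to 1
    (all k-mers) below 5000 reads and 8 above.
    """
    reads = _as_read_dict(reads)
    if not reads:
        raise ValueError("no reads supplied")
    if kmer_sample is None:
        kmer_sample = 1 if len(reads) < 5000 else 8
    g = nx.Graph()
    g.add_nodes_from(reads)

    if exact:
        aligner = make_local_aligner()
        ids = list(reads)
        for i, u in enumerate(ids):
            for v in ids[i + 1:]:
                min_ov = int(min_overlap_frac * min(len(reads[u]), len(reads[v])))
                hit = _exact_edge(reads[u], reads[v], min_identity, min_ov, aligner)
                if hit:
                    ident, ov, offset, same = hit
                    g.add_edge(u, v, identity=ident, overlap=ov,
                               offset=offset, same_strand=same, first=u)
        return ReadGraph(g, reads)

    # --- seeded mode -------------------------------------------------------
    # index: canonical kmer -> [(read, pos, is_forward)]
    bins: dict = {}
    keep = (lambda s: True) if kmer_sample <= 1 else \
        (lambda s: crc32(s.encode()) % kmer_sample == 0)
    for rid, seq in reads.items():
        for kmer, pos, fwd in canonical_kmers(seq, k):
            if keep(kmer):
                bins.setdefault(kmer, []).append((rid, pos, fwd))

    # gather diagonal evidence per ordered pair
    evidence: dict = {}
    order = {rid: i for i, rid in enumerate(reads)}
    for entries in bins.values():
        if len(entries) < 2:
            continue
        for i in range(len(entries)):
            ri, pi, fi = entries[i]
            for j in range(i + 1, len(entries)):
                rj, pj, fj = entries[j]
                if ri == rj:
                    continue
                if order[ri] < order[rj]:
                    a, pa, fa, b, pb, fb = ri, pi, fi, rj, pj, fj
                else:
                    a, pa, fa, b, pb, fb = rj, pj, fj, ri, pi, fi
                same = fa == fb
                if not same:  # b is matched on its reverse strand
                    pb = len(reads[b]) - k - pb
                offset = pa - pb
                key = (a, b, same)
                evidence.setdefault(key, set()).add(offset)

    checked: dict = {}
    for (a, b, same), offsets in evidence.items():
        sa = reads[a]
        sb = reads[b] if same else revcomp(reads[b])
        min_ov = int(min_overlap_frac * min(len(sa), len(sb)))
        best = checked.get((a, b))
        for offset in sorted(offsets):
            res = _overlap_identity(sa, sb, offset, min_ov)
            if res is None:
                continue
            ident, ov = res
            if ident >= min_identity and (best is None or ident > best[0]):
                best = (ident, ov, offset, same)
        if best is not None:
            checked[(a, b)] = best

    for (a, b), (ident, ov, offset, same) in checked.items():
        g.add_edge(a, b, identity=ident, overlap=ov, offset=offset,
                   same_strand=same, first=a)
    return ReadGraph(g, reads)


def connected_components(rg: ReadGraph) -> list:
    """Partition of the graph into clusters, largest first.

    ``genome_proportion`` is the cluster's share of all sampled
    nucleotides (singletons included in the denominator), in percent.
    """
    total_nt = sum(len(s) for s in rg.reads.values())
    comps = sorted(nx.connected_components(rg.graph),
                   key=lambda c: (-len(c), min(str(n) for n in c)))
    clusters = []
    for i, comp in enumerate(comps):
        members = sorted(comp, key=str)
        nt = sum(len(rg.reads[m]) for m in members)
        cl = RepeatCluster(cluster_id=i + 1, members=members,
                           genome_proportion=100.0 * nt / total_nt)
        cl.density = cluster_density(cl, rg)
        cl.shape = classify_shape(cl, rg)
        clusters.append(cl)
    return clusters


def cluster_density(cluster: RepeatCluster, rg: ReadGraph) -> float:
    """Mean number of links per read: 2E/V over the cluster subgraph."""
    if not cluster.members:
        raise ValueError("empty cluster")
    sub = rg.graph.subgraph(cluster.members)
    return 2.0 * sub.number_of_edges() / sub.number_of_nodes()


def _approx_diameter(sub: nx.Graph) -> int:
    """Two-sweep BFS diameter estimate (exact on trees, tight in practice)."""
    start = next(iter(sub.nodes))
    dist = nx.single_source_shortest_path_length(sub, start)
    far = max(dist, key=dist.get)
    dist2 = nx.single_source_shortest_path_length(sub, far)
    return max(dist2.values())


def classify_shape(cluster: RepeatCluster, rg: ReadGraph,
                   tau_linear: float = 0.5, ring_cover: float = 0.8) -> str:
    """Coarse cluster geometry: ``ring``, ``linear`` or ``globular``.

    Ring: the 2-core is a single cycle covering at least ``ring_cover`` of
    the nodes (checked first; an n-cycle also has diameter n/2 and would
    otherwise shadow into the linear rule). Linear: estimated graph
    diameter >= ``tau_linear`` * V, the signature of reads tiling a
    single-copy region. Everything else is globular.
    """
    members = cluster.members
    if len(members) < 3:
        return "linear"
    sub = rg.graph.subgraph(members)
    core = nx.k_core(sub, 2)
    if core.number_of_nodes() >= ring_cover * len(members) and \
            core.number_of_nodes() > 2 and \
            all(d == 2 for _n, d in core.degree()) and \
            nx.is_connected(core):
        return "ring"
    if _approx_diameter(sub) >= tau_linear * len(members):
        return "linear"
    return "globular"


def select_candidate_clusters(clusters,
                              density_threshold: float = DEFAULT_DENSITY_THRESHOLD):
    """Satellite candidates: globular or ring shape, density above threshold."""
    return [c for c in clusters
            if c.shape in ("globular", "ring") and c.density > density_threshold]
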