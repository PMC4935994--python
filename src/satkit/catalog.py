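"""Satellite catalog construction: variants, families, superfamilies, naming.

Classification follows the nested identity tiers standard for satellite
DNA: monomers above 95% identity are the same variant, above 80% they are
variants of one family, and families linked by a significant but weaker
alignment (>= 50 aligned bp at >= 60% identity by default) share a
superfamily. Identity is always maximised over monomer rotations and both
strands, and grouping uses single-linkage closure, which makes the result
independent of input order. Families are named
``<Abbrev>Sat<NN>-<monomer length>`` with catalog numbers assigned in
order of decreasing abundance in the reference sample.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import networkx as nx

from ._align import (make_local_aligner, local_alignment_pairs,
                     rotation_strand_identity, revcomp, stats_from_pairs)
from .tandem import ConsensusMonomer, canonical_rotation, at_content


@dataclass
class IdentityThresholds:
    same_variant: float = 95.0  # strictly above -> same variant
    same_family: float = 80.0   # strictly above -> same family
    superfamily_min_len: int = 50     # aligned bp for a significant hit
    superfamily_min_identity: float = 60.0

    def __post_init__(self):
        if self.same_variant <= self.same_family:
            raise ValueError("same_variant threshold must exceed same_family")


@dataclass
class SatVariant:
    seq: str
    family_id: int = -1
    variant_index: int = 1
    abundance: float = 0.0


@dataclass
class SatFamily:
    catalog_number: int = 0
    name: str = ""
    variants: list = field(default_factory=list)
    superfamily_id: int | None = None
    monomer_length: int = 0
    at_content: float = 0.0

    @property
    def abundance(self) -> float:
        return sum(v.abundance for v in self.variants)


def pairwise_identity(a, b) -> float:
    """Best end-to-end identity between two monomers, maximised over all
    rotations of ``a`` and both strands of ``b`` (symmetric)."""
    a = a.seq if isinstance(a, ConsensusMonomer) else a
    b = b.seq if isinstance(b, ConsensusMonomer) else b
    if not a or not b:
        raise ValueError("empty sequence")
    return float(rotation_strand_identity(a, b))


# Gap penalties are deliberately stiff: with lax gaps, maximal local
# alignments between unrelated monomers routinely reach 50 columns at 60%
# nominal identity, which would wire spurious superfamily links.
_SF_ALIGNER = make_local_aligner(match=1.0, mismatch=-1.0,
                                 gap_open=-4.0, gap_extend=-2.0)


def significant_similarity(a: str, b: str, min_len: int = 50,
                           min_identity: float = 60.0) -> bool:
    """Is there a local alignment of >= min_len bp at >= min_identity %?

    The query is doubled so that rotated matches spanning the monomer
    junction are found; both strands are searched.
    """
    query = a + a if len(a) < 2 * len(b) + 100 else a
    for target in (b, revcomp(b)):
        res = local_alignment_pairs(_SF_ALIGNER, query, target + target)
        if res is None:
            continue
        st = stats_from_pairs(res[0])
        aligned = min(st.columns, len(a), len(b))
        if aligned >= min_len and st.identity >= min_identity:
            return True
    return False


def _single_linkage(items, linked) -> list:
    """Groups under the transitive closure of the pairwise ``linked`` test."""
    g = nx.Graph()
    g.add_nodes_from(range(len(items)))
    for i, j in itertools.combinations(range(len(items)), 2):
        if linked(items[i], items[j]):
            g.add_edge(i, j)
    comps = sorted(nx.connected_components(g), key=min)
    return [sorted(c) for c in comps]


def group_catalog(monomers, thresholds: IdentityThresholds | None = None) -> list:
    """Classify (monomer, abundance) pairs into families of variants.

    Single-linkage at the variant threshold first (merged variants keep
    the most abundant representative and pool abundance), then at the
    family threshold, then superfamily linking by significant residual
    similarity. Families are returned ordered by decreasing abundance.
    """
    if not monomers:
        raise ValueError("empty catalog")
    thr = thresholds or IdentityThresholds()
    seqs = []
    for mono, ab in monomers:
        seq = mono.seq if isinstance(mono, ConsensusMonomer) else mono
        seqs.append((canonical_rotation(seq), float(ab)))

    ident_cache: dict = {}

    def ident(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key not in ident_cache:
            ident_cache[key] = rotation_strand_identity(x, y)
        return ident_cache[key]

    # variants: > same_variant identity collapses
    vgroups = _single_linkage(
        seqs, lambda p, q: ident(p[0], q[0]) > thr.same_variant)
    variants = []
    for grp in vgroups:
        members = [seqs[i] for i in grp]
        rep = max(members, key=lambda m: (m[1], m[0]))
        variants.append(SatVariant(seq=rep[0],
                                   abundance=sum(m[1] for m in members)))

    # families: > same_family identity among variant representatives
    fgroups = _single_linkage(
        variants, lambda p, q: ident(p.seq, q.seq) > thr.same_family)
    families = []
    for fid, grp in enumerate(fgroups):
        fam_variants = sorted((variants[i] for i in grp),
                              key=lambda v: (-v.abundance, v.seq))
        for vi, v in enumerate(fam_variants, 1):
            v.family_id = fid
            v.variant_index = vi
        top = fam_variants[0]
        families.append(SatFamily(variants=fam_variants,
                                  monomer_length=len(top.seq),
                                  at_content=at_content(top.seq)))

    # superfamilies: significant similarity at <= family-threshold identity
    def sf_linked(f1: SatFamily, f2: SatFamily) -> bool:
        for v1 in f1.variants:
            for v2 in f2.variants:
                if significant_similarity(v1.seq, v2.seq,
                                          thr.superfamily_min_len,
                                          thr.superfamily_min_identity):
                    return True
        return False

    sgroups = _single_linkage(families, sf_linked)
    sf_id = 0
    for grp in sgroups:
        if len(grp) < 2:
            continue
        sf_id += 1
        for i in grp:
            families[i].superfamily_id = sf_id

    families.sort(key=lambda f: (-f.abundance, -f.monomer_length,
                                 f.variants[0].seq))
    return families


NAME_RE = re.compile(r"^(?P<abbrev>[A-Z][a-z]+)Sat(?P<number>\d{2,})-(?P<length>\d+)"
                     r"(?:-(?P<suffix>[A-Za-z0-9]+))?$")


def name_families(families, species_abbrev: str,
                  suffixes: dict | None = None) -> list:
    """Assign ``<Abbrev>Sat<NN>-<length>`` names by decreasing abundance.

    Ties break deterministically: larger monomer first, then lexicographic
    consensus. ``suffixes`` optionally maps catalog numbers to a functional
    tag appended to the name (e.g. ``{7: "tel"}``).
    """
    if not re.match(r"^[A-Z][a-z]+$", species_abbrev):
        raise ValueError("species abbreviation must look like 'Lmi'")
    ordered = sorted(families, key=lambda f: (-f.abundance, -f.monomer_length,
                                              f.variants[0].seq))
    for i, fam in enumerate(ordered, 1):
        fam.catalog_number = i
        fam.name = f"{species_abbrev}Sat{i:02d}-{fam.monomer_length}"
        if suffixes and i in suffixes:
            fam.name += f"-{suffixes[i]}"
    return ordered


def parse_family_name(name: str) -> dict:
    m = NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a valid satellite family name: {name!r}")
    d = m.groupdict()
    return {"abbrev": d["abbrev"], "catalog_number": int(d["number"]),
            "monomer_length": int(d["length"]), "suffix": d["suffix"]}


# ---------------------------------------------------------------------------
# minimum spanning tree within a superfamily

def variant_distance(a: str, b: str, indel_mode: str = "events") -> dict:
    """Substitution/indel distance between two aligned variants.

    The alignment maximises rotation/strand identity; the distance is
    substitutions plus indel EVENTS (a contiguous gap run counts once) by
    default, or plus gap columns with ``indel_mode='positions'``. The
    nucleotide total across indels is reported separately.
    """
    _ident, st = rotation_strand_identity(a, b, with_stats=True)
    if indel_mode == "events":
        indel_cost = st.indel_events
    elif indel_mode == "positions":
        indel_cost = st.indel_nt
    else:
        raise ValueError("indel_mode must be 'events' or 'positions'")
    return {"s": st.substitutions, "id": st.indel_events, "id_nt": st.indel_nt,
            "weight": st.substitutions + indel_cost}


def build_mst(variants, indel_mode: str = "events") -> nx.Graph:
    """Minimum spanning tree over variants (nodes) with edges annotated
    ``s`` (substitutions), ``id`` (indel events) and ``id_nt`` (indel bp)."""
    seqs = [v.seq if isinstance(v, SatVariant) else v for v in variants]
    if len(seqs) < 2:
        raise ValueError("at least two variants are required")
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    for i, j in itertools.combinations(range(len(seqs)), 2):
        d = variant_distance(seqs[i], seqs[j], indel_mode)
        g.add_edge(i, j, **d)
    return nx.minimum_spanning_tree(g, weight="weight")
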