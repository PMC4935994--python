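"""Variant / family / superfamily classification and naming.

Starts from four monomers: two variants of one family (97% identity), a
distant relative (a superfamily partner at ~70%) and an unrelated
sequence. Groups them with the standard identity tiers (>95% same
variant, >80% same family, significant weaker similarity -> same
superfamily), names families by decreasing abundance and prints the
minimum spanning tree of the superfamily.
"""

import numpy as np

from satkit.catalog import build_mst, group_catalog, name_families

rng = np.random.default_rng(5)


def mutate(seq, n):
    s = list(seq)
    for p in rng.choice(len(s), n, replace=False):
        s[p] = "ACGT"[("ACGT".index(s[p]) + 1 + int(rng.integers(3))) % 4]
    return "".join(s)


base = "".join(rng.choice(list("ACGT"), 200))
inputs = [
    (base, 0.80),            # most abundant
    (mutate(base, 6), 0.30),  # ~97%: same variant, abundance pools
    (mutate(base, 60), 0.10),  # ~70%: separate family, same superfamily
    ("".join(rng.choice(list("ACGT"), 150)), 0.05),  # unrelated
]

families = name_families(group_catalog(inputs), "Sim")
for fam in families:
    sf = fam.superfamily_id if fam.superfamily_id else "-"
    print(f"{fam.name:<14} abundance {fam.abundance:.2f}%  "
          f"variants {len(fam.variants)}  A+T {fam.at_content:.1f}%  SF {sf}")

sf_variants = [v for f in families if f.superfamily_id == 1 for v in f.variants]
tree = build_mst(sf_variants)
print("\nsuperfamily 1 minimum spanning tree:")
for u, v, d in tree.edges(data=True):
    print(f"  {sf_variants[u].seq[:12]}... -- {sf_variants[v].seq[:12]}...  "
          f"s={d['s']} id={d['id']} ({d['id_nt']} nt)")
# Edge labels: s substitutions and id indel events (with the nucleotides
# involved in brackets), the same distance used to draw repeat networks.
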