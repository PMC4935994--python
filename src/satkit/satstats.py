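"""Satellitome-level statistics from an annotation table.

The annotation table is one row per satellite family: monomer length,
A+T content, number of sequence variants, abundance and mean K2P
divergence per sequenced sample, number of assembly contigs carrying the
family, maximum repeats per contig, the FISH location tokens per
chromosome (p = proximal, i = interstitial, d = distal, t = telomeric)
and the cytological pattern (c = clustered, nc = non-clustered,
m = mixed). A transcription of the Locusta migratoria satellitome
(62 families, 12 chromosome pairs) ships with the package and is the
default table.

The "working set" excludes families flagged in the table metadata (the
telomeric repeat, whose function is known, and families that could not be
confirmed by PCR), leaving the 58 families used for the descriptive and
inferential statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

CHROMOSOMES = ["L1", "L2", "X", "M3", "M4", "M5", "M6", "M7", "M8",
               "S9", "S10", "S11"]
LOCATION_TOKENS = {"p", "i", "d", "t"}
PATTERNS = {"c", "nc", "m", "none"}
TELOMERIC_FAMILY = "LmiSat07-5-tel"


class AnnotationError(ValueError):
    pass


@dataclass
class SatellitomeSummary:
    n_proximal: int
    n_interstitial: int
    n_distal: int
    total_loci: int
    n_clustered_families: int
    n_chromosomes: int
    clusters_per_satdna: float
    clusters_per_chromosome: float


def load_annotation_table(path=None) -> pd.DataFrame:
    """Load an annotation TSV; defaults to the packaged locust satellitome."""
    if path is None:
        source = resources.files("satkit.data") / "locusta_satellitome.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    for col in CHROMOSOMES:
        df[col] = df[col].fillna("").astype(str).str.strip()
    df["pattern"] = df["pattern"].fillna("none").astype(str).str.strip()
    for i, row in df.iterrows():
        if row["pattern"] not in PATTERNS:
            raise AnnotationError(
                f"row {row['family']}: unknown pattern {row['pattern']!r}")
        for c in CHROMOSOMES:
            for tok in _tokens(row[c]):
                if tok not in LOCATION_TOKENS:
                    raise AnnotationError(
                        f"row {row['family']}: unknown location token {tok!r}")
    if "in_working_set" not in df.columns:
        df["in_working_set"] = True
    return df


def _tokens(cell: str):
    cell = cell.strip()
    return [t.strip() for t in cell.split(",") if t.strip()] if cell else []


def working_set(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["in_working_set"]].reset_index(drop=True)


def family_locations(row) -> dict:
    """Chromosome -> list of location tokens for one table row."""
    return {c: _tokens(row[c]) for c in CHROMOSOMES if _tokens(row[c])}


def summarize_locations(df: pd.DataFrame,
                        exclude=(TELOMERIC_FAMILY,)) -> SatellitomeSummary:
    """Cluster-location census over clustered/mixed families.

    Counts each p/i/d token once per chromosome entry; ``exclude`` names
    families left out (default: the telomeric repeat, whose tokens are
    telomeric on every chromosome anyway).
    """
    sub = df[~df["family"].isin(set(exclude))]
    counts = {"p": 0, "i": 0, "d": 0}
    n_clustered = 0
    for _i, row in sub.iterrows():
        if row["pattern"] not in ("c", "m"):
            continue
        n_clustered += 1
        for toks in family_locations(row).values():
            for t in toks:
                if t in counts:
                    counts[t] += 1
    total = sum(counts.values())
    return SatellitomeSummary(
        n_proximal=counts["p"], n_interstitial=counts["i"], n_distal=counts["d"],
        total_loci=total, n_clustered_families=n_clustered,
        n_chromosomes=len(CHROMOSOMES),
        clusters_per_satdna=total / n_clustered if n_clustered else float("nan"),
        clusters_per_chromosome=total / len(CHROMOSOMES))


def length_distribution(df: pd.DataFrame, min_group: int = 2):
    """Bimodality of monomer lengths: the largest inter-length gap that
    splits the families into two groups of at least ``min_group``.

    Returns (n_short, n_long, gap, (low, high)); with fewer than two
    distinct lengths there is no gap and (n, 0, 0, None) is returned.
    A gap isolating fewer than ``min_group`` families (a lone outlier)
    does not count as a mode split.
    """
    lengths = sorted(df["monomer_length"])
    distinct = sorted(set(lengths))
    if len(distinct) < 2:
        return len(lengths), 0, 0, None
    best = None
    for a, b in zip(distinct, distinct[1:]):
        n_short = sum(1 for x in lengths if x <= a)
        n_long = sum(1 for x in lengths if x >= b)
        if min(n_short, n_long) < min_group:
            continue
        if best is None or b - a > best[2]:
            best = (n_short, n_long, b - a, (a, b))
    if best is None:
        return len(lengths), 0, 0, None
    return best


def spearman_rho(x, y):
    """Spearman rank correlation (average ranks for ties).

    Returns (rho, p); rho is nan for constant input.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def mann_whitney_u(a, b):
    """Mann-Whitney U (the smaller of U1/U2, ties at half credit).

    Returns (U, p) with an exact/two-sided p from the normal
    approximation with tie correction for larger samples.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    u1 = float(res.statistic)
    u = min(u1, len(a) * len(b) - u1)
    return u, float(res.pvalue)


def abundance_contig_correlation(df: pd.DataFrame, column: str = "abundance_nl"):
    """Spearman correlation between family abundance and the number of
    draft-genome contigs carrying the family, over the working set.

    Families lacking an abundance estimate in the chosen sample (absent
    from that individual) enter as zero. The contig counts come from the
    Northern-lineage draft assembly, so the Northern abundance column is
    the default.
    """
    ws = working_set(df)
    x = ws[column].fillna(0.0)
    y = ws["n_contigs"]
    rho, p = spearman_rho(x, y)
    return rho, p, len(ws)


def clustered_vs_nonclustered_contigs(df: pd.DataFrame):
    """Mann-Whitney U comparing contig counts of clustered (c or m) vs
    non-clustered (nc) families over the working set."""
    ws = working_set(df)
    a = ws.loc[ws["pattern"].isin(["c", "m"]), "n_contigs"]
    b = ws.loc[ws["pattern"] == "nc", "n_contigs"]
    return mann_whitney_u(a, b)


def chromosome_specific(df: pd.DataFrame, exclude=(TELOMERIC_FAMILY,)) -> list:
    """Clustered/mixed families whose clusters sit on exactly one chromosome."""
    out = []
    for _i, row in df[~df["family"].isin(set(exclude))].iterrows():
        if row["pattern"] not in ("c", "m"):
            continue
        if len(family_locations(row)) == 1:
            out.append(row["family"])
    return out


def satellitome_report(df: pd.DataFrame | None = None) -> dict:
    """The headline satellitome statistics in one dictionary."""
    if df is None:
        df = load_annotation_table()
    ws = working_set(df)
    summary = summarize_locations(ws)
    n_short, n_long, gap, bounds = length_distribution(ws)
    rho, rho_p, n = abundance_contig_correlation(df)
    u, u_p = clustered_vs_nonclustered_contigs(df)
    return {
        "n_families": len(df),
        "n_working_set": len(ws),
        "total_variants": int(df["n_variants"].sum()),
        "abundance_sl_total": float(df["abundance_sl"].sum()),
        "abundance_nl_total": float(df["abundance_nl"].sum()),
        "proximal": summary.n_proximal,
        "interstitial": summary.n_interstitial,
        "distal": summary.n_distal,
        "total_loci": summary.total_loci,
        "clusters_per_satdna": summary.clusters_per_satdna,
        "clusters_per_chromosome": summary.clusters_per_chromosome,
        "n_short": n_short, "n_long": n_long,
        "length_gap": gap, "length_gap_bounds": bounds,
        "spearman_abundance_contigs": rho, "spearman_p": rho_p, "spearman_n": n,
        "mann_whitney_u": u, "mann_whitney_p": u_p,
        "n_chromosome_specific": len(chromosome_specific(ws)),
    }
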