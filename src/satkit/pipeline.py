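"""End-to-end orchestration: QC -> iterative mining -> catalog -> quantification.

Every artifact is stamped with a hash of the configuration and the seed,
and all randomness flows from the configured seeds, so a rerun with an
identical configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import catalog as catalog_mod
from . import quantify as quantify_mod
from .mining import satminer_loop
from .seqio import QCParams, read_fastq_pairs, trim_and_filter_pairs, write_fasta

log = logging.getLogger("satkit")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    in1: str = ""
    in2: str = ""
    outdir: str = "satkit_out"
    seed: int = 1
    species_abbrev: str = "Xxx"
    # QC
    qc_window: int = 4
    qc_min_mean_q: float = 20.0
    qc_min_len: int = 100
    # clustering / mining
    min_identity: float = 90.0
    min_overlap_frac: float = 0.55
    density_threshold: float = 0.1
    schedule: tuple = (250_000, 500_000, 500_000, 500_000)
    # classification
    same_variant: float = 95.0
    same_family: float = 80.0
    # quantification
    quant_pairs: int | None = None  # pairs used for abundance (default: all)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig, pairs=None) -> dict:
    """Run the full discovery pipeline; returns a dict of artifact paths.

    ``pairs`` may inject an in-memory list of read pairs (e.g. simulated
    ones); otherwise the FASTQ files named in the config are read.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    # --- qc ---------------------------------------------------------------
    if pairs is None:
        if not config.in1 or not config.in2:
            raise StageError("qc", "no input reads supplied")
        pairs = list(read_fastq_pairs(config.in1, config.in2))
    if not pairs:
        raise StageError("qc", "input read set is empty")
    params = QCParams(window=config.qc_window, min_mean_q=config.qc_min_mean_q,
                      min_len=config.qc_min_len)
    clean = list(trim_and_filter_pairs(pairs, params))
    log.info("qc: %d of %d pairs pass", len(clean), len(pairs))
    if not clean:
        raise StageError("qc", "no read pair passed quality filtering")

    # --- mining -----------------------------------------------------------
    state = satminer_loop(clean, list(config.schedule), config.seed,
                          min_identity=config.min_identity,
                          min_overlap_frac=config.min_overlap_frac,
                          density_threshold=config.density_threshold, log=log)
    mining_tsv = outdir / "mining.tsv"
    with open(mining_tsv, "w") as fh:
        fh.write("iteration\treads_used\tclusters_examined\tnew_satellites\n")
        for h in state.history:
            fh.write(f"{h['iteration']}\t{2 * h['reads_used']}\t"
                     f"{h['clusters_examined']}\t{h['new_satellites']}\n")

    artifacts = {"mining_report": str(mining_tsv), "state": state, **stamp}
    if not state.known_satellites:
        log.info("no satellites found; stopping after mining stage")
        return artifacts

    # --- abundance for naming + catalog ------------------------------------
    quant_pairs = clean if config.quant_pairs is None else clean[:config.quant_pairs]
    reads = {}
    for p in quant_pairs:
        reads[f"{p.id}/1"] = p.seq1
        reads[f"{p.id}/2"] = p.seq2
    total_nt = sum(len(s) for s in reads.values())
    provisional = [(f"sat{i}", m) for i, m in enumerate(state.known_satellites)]
    library = quantify_mod.build_library(provisional)
    hits = quantify_mod.align_reads_to_library(reads, library)
    quants = {q.family: q for q in
              quantify_mod.family_abundance(hits, total_nt, library)}
    abundances = [quants[f"sat{i}"].abundance if f"sat{i}" in quants else 0.0
                  for i in range(len(state.known_satellites))]

    thresholds = catalog_mod.IdentityThresholds(
        same_variant=config.same_variant, same_family=config.same_family)
    families = catalog_mod.group_catalog(
        list(zip(state.known_satellites, abundances)), thresholds)
    families = catalog_mod.name_families(families, config.species_abbrev)

    catalog_fa = outdir / "catalog.fasta"
    write_fasta({f"{fam.name}#{v.variant_index}": v.seq
                 for fam in families for v in fam.variants}, catalog_fa)
    catalog_tsv = outdir / "catalog.tsv"
    with open(catalog_tsv, "w") as fh:
        fh.write("family\tvariant\tmonomer_length\tat_content\tsuperfamily\t"
                 "abundance\n")
        for fam in families:
            for v in fam.variants:
                sf = fam.superfamily_id if fam.superfamily_id else ""
                fh.write(f"{fam.name}\t{v.variant_index}\t{fam.monomer_length}\t"
                         f"{fam.at_content:.2f}\t{sf}\t{v.abundance:.5f}\n")

    # --- final quantification against the named catalog ---------------------
    library = quantify_mod.build_library(families)
    hits = quantify_mod.align_reads_to_library(reads, library)
    quants = quantify_mod.family_abundance(hits, total_nt, library)
    quant_tsv = outdir / "quantification.tsv"
    with open(quant_tsv, "w") as fh:
        fh.write("family\tabundance_pct\tmean_divergence_pct\n")
        for q in quants:
            div = "" if q.mean_divergence != q.mean_divergence else \
                f"{q.mean_divergence:.3f}"
            fh.write(f"{q.family}\t{q.abundance:.5f}\t{div}\n")
    landscape_tsv = outdir / "landscape.tsv"
    with open(landscape_tsv, "w") as fh:
        bins = quantify_mod.SATURATION_BIN + 1
        fh.write("family\t" + "\t".join(f"bin_{i}" for i in range(bins)) + "\n")
        for q in quants:
            fh.write(q.family + "\t" +
                     "\t".join(f"{x:.6f}" for x in q.landscape) + "\n")

    with open(outdir / "run.json", "w") as fh:
        json.dump({**stamp,
                   "iterations": state.iteration,
                   "n_families": len(families),
                   "converged": state.converged}, fh, indent=1)

    artifacts.update(catalog_fasta=str(catalog_fa), catalog_tsv=str(catalog_tsv),
                     quantification=str(quant_tsv), landscape=str(landscape_tsv),
                     families=families)
    return artifacts
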