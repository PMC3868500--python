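"""End-to-end orchestration: simulate/clean/map/profile/diffexp/basedit/qpcr/cluster.

``run_pipeline`` drives every stage on either simulated or user-supplied
inputs, writes all report tables to the output directory, and records a
manifest with versions, the seed, stage parameters, and per-stage
conservation checks (reads in = clean + removed; known + unannotated =
clean; DE and edit partitions sum to their table sizes).  The whole run is
deterministic under a fixed seed and config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from . import basedit as be
from . import cluster as cl
from . import diffexp as de
from . import mapping as mp
from . import profiling as pr
from . import qpcr as qp
from . import simulate as sim
from . import tags as tg

logger = logging.getLogger("smallrna_dx")


@dataclass
class PipelineConfig:
    """Everything one run needs; synthetic mode when no FASTQ paths given."""

    outdir: str = "smallrna_dx_out"
    # synthetic mode
    simulation: Optional[sim.SimulationConfig] = None
    n_pairs: int = 4  # sample pairs for the cluster stage (pair 1 = main)
    # explicit-input mode
    fastq_nc: Optional[str] = None
    fastq_mn: Optional[str] = None
    genome_fasta: Optional[str] = None
    mirna_fasta: Optional[str] = None
    ct_table: Optional[str] = None
    # stage parameters
    adaptor_3p: str = sim.DEFAULT_ADAPTOR_3P
    adaptor_5p: Optional[str] = None
    min_mean_quality: float = tg.DEFAULT_MIN_MEAN_QUALITY
    max_n_fraction: float = tg.DEFAULT_MAX_N_FRACTION
    min_insert: int = tg.DEFAULT_MIN_INSERT
    max_insert: int = tg.DEFAULT_MAX_INSERT
    p_threshold: float = de.DEFAULT_P_THRESHOLD
    fc_threshold: float = de.DEFAULT_FC_THRESHOLD
    p_mode: de.PValueMode = "point"
    distance: cl.Distance = "euclidean"
    linkage: cl.Linkage = "average"
    write_plots: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        explicit = [self.fastq_nc, self.fastq_mn, self.genome_fasta, self.mirna_fasta]
        if self.simulation is None:
            if any(p is None for p in explicit):
                raise ValueError(
                    "config needs either a simulation block or all of "
                    "fastq_nc/fastq_mn/genome_fasta/mirna_fasta"
                )
            for p in explicit + ([self.ct_table] if self.ct_table else []):
                if p and not Path(p).exists():
                    raise FileNotFoundError(f"configured input does not exist: {p}")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass
class PipelineResult:
    outdir: Path
    libraries: Dict[str, tg.TagLibrary]
    mapping_summaries: Dict[str, mp.MappingSummary]
    count_table: pr.CountTable
    de_records: List[de.DERecord]
    de_summary: dict
    edit_summaries: List[be.EditSummary]
    edit_partition: Tuple[int, int, int]
    pair_matrix: Optional[object] = None
    cluster_result: Optional[cl.ClusterResult] = None
    qpcr_concordance: Optional[float] = None
    manifest: dict = field(default_factory=dict)
    truth: Optional[sim.GroundTruth] = None


def _analyze_pair(
    reads_nc: Sequence[tg.Read],
    reads_mn: Sequence[tg.Read],
    reference: Sequence[pr.MatureMiRNA],
    config: PipelineConfig,
) -> Tuple[Dict[str, tg.TagLibrary], Dict[str, tg.CleaningReport], pr.CountTable, List[de.DERecord], dict, Dict[str, Dict[str, int]]]:
    """Clean both libraries, count known miRNAs, run DE; return intermediates."""
    libraries: Dict[str, tg.TagLibrary] = {}
    reports: Dict[str, tg.CleaningReport] = {}
    for lib_id, reads in (("NC", reads_nc), ("MN", reads_mn)):
        lib, report = tg.clean_reads(
            reads,
            lib_id,
            adaptor_3p=config.adaptor_3p,
            adaptor_5p=config.adaptor_5p,
            min_mean_quality=config.min_mean_quality,
            max_n_fraction=config.max_n_fraction,
            min_insert=config.min_insert,
            max_insert=config.max_insert,
        )
        libraries[lib_id] = lib
        reports[lib_id] = report
    known: Dict[str, Dict[str, int]] = {}
    unannotated: Dict[str, Dict[str, int]] = {}
    for lib_id, lib in libraries.items():
        known[lib_id], unannotated[lib_id] = pr.count_known(lib.tags, reference)
    table = pr.build_count_table(
        known["NC"], known["MN"],
        n1=libraries["NC"].total_clean, n2=libraries["MN"].total_clean,
    )
    records, summary = de.differential_table(
        table, mode=config.p_mode,
        p_threshold=config.p_threshold, fc_threshold=config.fc_threshold,
    )
    return libraries, reports, table, records, summary, unannotated


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage, write all tables + manifest, return in-memory results."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "smallrna-dx",
        "version": __version__,
        "rng_seed": config.rng_seed,
        "parameters": {
            "adaptor_3p": config.adaptor_3p,
            "min_mean_quality": config.min_mean_quality,
            "max_n_fraction": config.max_n_fraction,
            "insert_bounds": [config.min_insert, config.max_insert],
            "p_threshold": config.p_threshold,
            "fc_threshold": config.fc_threshold,
            "p_mode": config.p_mode,
            "distance": config.distance,
            "linkage": config.linkage,
        },
        "stages": {},
        "conservation": {},
    }
    truth: Optional[sim.GroundTruth] = None

    # ---- inputs: simulate or load ------------------------------------
    if config.simulation is not None:
        simcfg = config.simulation
        genome = sim.generate_genome(
            simcfg.n_chromosomes, simcfg.chrom_length, simcfg.rng_seed
        )
        mirna_ref_seqs, truth = sim.plant_mirnas(genome, simcfg)
        reads_nc, reads_mn, truth = sim.simulate_libraries(mirna_ref_seqs, simcfg, truth)
        reference = [pr.MatureMiRNA(n, s) for n, s in mirna_ref_seqs]
        manifest["stages"]["simulate"] = {
            "n_mirnas": simcfg.n_mirnas,
            "library_depths": list(simcfg.library_depths),
            "contamination_rate": simcfg.contamination_rate,
            "seed_edit_rate": simcfg.seed_edit_rate,
        }
    else:
        genome = mp.read_fasta(config.genome_fasta)
        reference = pr.load_mature_reference(config.mirna_fasta)
        mirna_ref_seqs = [(m.name, m.sequence) for m in reference]
        reads_nc = list(tg.read_fastq(config.fastq_nc))
        reads_mn = list(tg.read_fastq(config.fastq_mn))

    # ---- clean + profile + DE on the primary pair --------------------
    libraries, reports, table, records, de_summary, unannotated = _analyze_pair(
        reads_nc, reads_mn, reference, config
    )
    for lib_id in ("NC", "MN"):
        reports[lib_id].check_conservation()
        manifest["stages"][f"clean_{lib_id}"] = tg.cleaning_report_dict(
            reports[lib_id], libraries[lib_id]
        )
        tg.write_tags_tsv(libraries[lib_id], outdir / f"tags_{lib_id}.tsv")
        manifest["conservation"][f"reads_{lib_id}"] = (
            reports[lib_id].n_input
            == reports[lib_id].n_clean + sum(reports[lib_id].removed.values())
        )

    # ---- genome mapping ----------------------------------------------
    index = mp.build_index(genome)
    summaries: Dict[str, mp.MappingSummary] = {}
    for lib_id, lib in libraries.items():
        hits = mp.map_library(lib.tags, index)
        summaries[lib_id] = mp.mapping_summary(lib_id, lib.tags, hits)
        mp.write_hits_tsv(hits, lib.tags, outdir / f"hits_{lib_id}.tsv")
        manifest["stages"][f"map_{lib_id}"] = mp.summary_dict(summaries[lib_id])
    with open(outdir / "mapping_summary.json", "w") as fh:
        json.dump(
            {k: mp.summary_dict(v) for k, v in summaries.items()}, fh, indent=1
        )

    # ---- profiling ----------------------------------------------------
    pr.write_count_table(table, outdir / "counts.tsv")
    for lib_id, lib in libraries.items():
        assigned = {
            seq: count
            for seq, count in lib.tags.items()
            if seq not in unannotated[lib_id]
        }
        comp = pr.base_composition(assigned, group=lib_id)
        if not comp.matrix.empty:
            pr.write_composition(comp, outdir / f"base_composition_{lib_id}.tsv")
        manifest["conservation"][f"counts_{lib_id}"] = (
            sum(table.counts[lib_id]) + sum(unannotated[lib_id].values())
            == lib.total_clean
        )

    # ---- differential expression --------------------------------------
    de.write_de_table(records, outdir / "diffexp.tsv")
    ups, downs = de.top_tables(records, 20)
    de.write_de_table(ups + downs, outdir / "diffexp_top.tsv")
    with open(outdir / "diffexp_summary.json", "w") as fh:
        json.dump(de_summary, fh, indent=1)
    manifest["stages"]["diffexp"] = de_summary
    manifest["conservation"]["de_partition"] = (
        de_summary["n_up"] + de_summary["n_down"] + de_summary["n_unchanged"]
        == de_summary["n_total"]
    )

    # ---- seed edits ----------------------------------------------------
    edited: Dict[str, Dict[str, int]] = {}
    hits_out: List[be.SeedEditHit] = []
    known_counts = {
        lib_id: dict(zip(table.counts.index, table.counts[lib_id]))
        for lib_id in ("NC", "MN")
    }
    for lib_id in ("NC", "MN"):
        edited[lib_id], hits = be.tally_seed_edits(unannotated[lib_id], reference)
        hits_out.extend(hits)
    edit_summaries, skipped = be.summarize_edits(
        exact_mn=known_counts["MN"], edited_mn=edited["MN"],
        exact_nc=known_counts["NC"], edited_nc=edited["NC"],
    )
    partition = be.edit_partition(edit_summaries)
    be.write_edit_summary(edit_summaries, outdir / "seed_edits.tsv")
    be.write_edit_hits(hits_out, outdir / "seed_edit_hits.tsv")
    n_classified = sum(1 for s in edit_summaries if s.edit_class is not None)
    manifest["stages"]["basedit"] = {
        "n_gt1": partition[0], "n_eq1": partition[1], "n_lt1": partition[2],
        "n_skipped_zero_denominator": len(skipped),
    }
    manifest["conservation"]["edit_partition"] = sum(partition) == n_classified

    # ---- additional sample pairs + clustering -------------------------
    pair_records: Dict[str, List[de.DERecord]] = {"pair01": records}
    if config.simulation is not None and config.n_pairs > 1:
        for k in range(2, config.n_pairs + 1):
            sub = sim.SimulationConfig(
                n_chromosomes=config.simulation.n_chromosomes,
                chrom_length=config.simulation.chrom_length,
                n_mirnas=config.simulation.n_mirnas,
                mirna_length_range=config.simulation.mirna_length_range,
                library_depths=config.simulation.library_depths,
                log2_effects=config.simulation.log2_effects,
                seed_edit_rate=config.simulation.seed_edit_rate,
                contamination_rate=config.simulation.contamination_rate,
                adaptor_3p=config.simulation.adaptor_3p,
                read_length=config.simulation.read_length,
                rng_seed=config.simulation.rng_seed + 1000 * k,
            )
            nc_k, mn_k, _ = sim.simulate_libraries(mirna_ref_seqs, sub)
            _, _, _, recs_k, _, _ = _analyze_pair(nc_k, mn_k, reference, config)
            pair_records[f"pair{k:02d}"] = recs_k
    matrix = cl.build_pair_matrix(pair_records)
    result_cluster: Optional[cl.ClusterResult] = None
    if matrix.shape[0] >= 2 and matrix.shape[1] >= 2:
        try:
            result_cluster = cl.cluster(matrix, config.distance, config.linkage)
            cl.write_heatmap_tsv(matrix, result_cluster, outdir / "heatmap.tsv")
            if config.write_plots:
                cl.plot_heatmap(matrix, result_cluster, outdir / "heatmap.png")
        except ValueError as exc:
            logger.warning("cluster stage skipped: %s", exc)
    else:
        matrix.to_csv(outdir / "heatmap.tsv", sep="\t", na_rep="NA")

    # ---- qPCR concordance ----------------------------------------------
    qpcr_fraction: Optional[float] = None
    if config.ct_table:
        qrecords = qp.read_ct_table(config.ct_table)
        qp.write_qpcr_table(qrecords, outdir / "qpcr.tsv")
        fc_map = {r.mirna: r.fold_change for r in records}
        agree_df, qpcr_fraction = qp.concordance(qrecords, fc_map)
        agree_df.to_csv(outdir / "qpcr_concordance.tsv", sep="\t")
        manifest["stages"]["qpcr"] = {
            "n_mirnas": len(qrecords), "concordant_fraction": qpcr_fraction,
        }

    if truth is not None:
        sim.write_ground_truth(truth, outdir)
    if not all(manifest["conservation"].values()):
        failed = [k for k, v in manifest["conservation"].items() if not v]
        raise RuntimeError(f"conservation checks failed: {failed}")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return PipelineResult(
        outdir=outdir,
        libraries=libraries,
        mapping_summaries=summaries,
        count_table=table,
        de_records=records,
        de_summary=de_summary,
        edit_summaries=edit_summaries,
        edit_partition=partition,
        pair_matrix=matrix,
        cluster_result=result_cluster,
        qpcr_concordance=qpcr_fraction,
        manifest=manifest,
        truth=truth,
    )
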