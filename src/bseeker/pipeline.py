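"""End-to-end orchestration of the B-chromosome gene-detection stages.

A run starts from a simulated bundle (or previously written inputs),
converts depth to copy number, applies the copy filter and gFC selection,
segments candidate coverage patterns, calls B-specific SNPs on the
candidates, quantifies B-paralog expression at passing SNPs, validates
B-linkage from the qPCR tables, and scores every stage against the
ground-truth manifest.  All stage outputs are pure functions of
(inputs, config, seed); the run manifest records the config snapshot and
a checksum per output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import candidate_selection as sel
from . import copy_number as cn
from . import expression as expr
from . import qpcr_stats as qpcr
from . import snp_calling as snp
from . import synthetic_data as synth
from .io_formats import write_segments_bed, write_snp_vcf

#: fixed per-stage seed offsets fanned out from the top-level seed
STAGE_SEED_OFFSETS = {"simulate": 0, "qpcr": 1009}


@dataclass
class RunManifest:
    seed: int
    config: dict
    outputs: dict = field(default_factory=dict)    # name -> path
    checksums: dict = field(default_factory=dict)  # name -> sha256
    summary: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    manifest: RunManifest
    dataset: synth.SimulatedDataset
    copy_table: pd.DataFrame
    gfc_records: list
    candidates: set
    segments: dict        # contig -> (list[Segment], pattern)
    snp_calls: list
    expression: pd.DataFrame
    qpcr_validation: pd.DataFrame
    recovery: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | None = None, out_dir=None, seed: int = 0) -> PipelineResult:
    """Run every stage on a (simulated) dataset; optionally write artifacts.

    ``config`` may carry ``simulate`` (SimulationConfig fields), ``selection``
    (SelectionConfig fields) and ``snp`` (SnpCallConfig fields) blocks.
    """
    config = dict(config or {})
    sim_kwargs = dict(config.get("simulate", {}))
    sim_kwargs["seed"] = seed + STAGE_SEED_OFFSETS["simulate"]
    sim_cfg = synth.SimulationConfig(**sim_kwargs)
    sel_cfg = sel.SelectionConfig(**config.get("selection", {}))
    snp_cfg = snp.SnpCallConfig(**config.get("snp", {}))

    ds = synth.simulate_dataset(sim_cfg)
    model = sim_cfg.genome_model()

    # --- copy number --------------------------------------------------------
    copy_table = cn.copy_number_table(
        ds.depth_tracks.values(), ds.libraries, ds.contigs, model, region="cds"
    )

    # --- copy filter + gFC + selection --------------------------------------
    kept = sel.copy_filter(copy_table, ds.libraries, sel_cfg)
    lib_by_id = {l.library_id: l for l in ds.libraries}
    pivot = copy_table.pivot(index="contig_id", columns="library_id",
                             values="copies_per_haploid")
    ids_0B = sorted(l.library_id for l in ds.libraries
                    if l.molecule == "gDNA" and l.b_count == 0)
    ids_1B = sorted(l.library_id for l in ds.libraries
                    if l.molecule == "gDNA" and l.b_count == 1)
    gfc_records = []
    for contig in sorted(kept):
        rec = sel.compute_gfc(
            contig,
            pivot.loc[contig, ids_1B].to_numpy(),
            pivot.loc[contig, ids_0B].to_numpy(),
        )
        gfc_records.append(rec)
    candidates = sel.select_candidates(gfc_records, sel_cfg, n_1B=len(ids_1B))

    # --- coverage-pattern segmentation of candidates ------------------------
    segments = {}
    tracks_by_contig_0B = {}
    tracks_by_contig_1B = {}
    for (lib_id, contig), track in ds.depth_tracks.items():
        lib = lib_by_id[lib_id]
        target = tracks_by_contig_1B if lib.b_count == 1 else tracks_by_contig_0B
        target.setdefault(contig, []).append(track)
    for contig in sorted(candidates):
        ratio = sel.pooled_ratio(
            tracks_by_contig_1B[contig], tracks_by_contig_0B[contig], ds.libraries
        )
        segs, pattern = sel.classify_pattern(contig, ratio, sel_cfg)
        segments[contig] = (segs, pattern)
        for rec in gfc_records:
            if rec.contig_id == contig:
                rec.pattern = pattern

    # --- B-specific SNP calling on candidates -------------------------------
    snp_calls = []
    for contig in sorted(candidates):
        snp_calls.extend(
            snp.call_b_snps(ds.group_pileups[contig], ds.cross_pileups[contig], snp_cfg)
        )
    snp_calls = snp.merge_indel_events(snp_calls)

    # --- expression at passing SNPs -----------------------------------------
    gene_of_contig = {c.contig_id: (c.gene_name or c.contig_id) for c in ds.contigs}
    length_of_contig = {c.contig_id: c.length for c in ds.contigs}
    passing_by_contig = {}
    for call in snp_calls:
        if call.verdict == "PASS":
            passing_by_contig.setdefault(call.contig_id, []).append(call)
    expr_records = []
    for contig, calls in sorted(passing_by_contig.items()):
        for lib_id, pile in sorted(ds.rna_pileups[contig].items()):
            rec = expr.count_alleles_at_snps(
                pile, calls, gene_of_contig[contig], length_of_contig[contig],
                library_id=lib_id,
            )
            if rec is not None:
                expr_records.append(rec)
    expression_df = expr.expression_table(expr_records)

    # --- qPCR validation ----------------------------------------------------
    qpcr_seed = seed + STAGE_SEED_OFFSETS["qpcr"]
    qpcr_validation = qpcr.validate_genes(ds.ct_gdna, seed=qpcr_seed)

    # --- recovery scoring ---------------------------------------------------
    genes = ds.manifest.genes
    truth_contigs = set(
        genes.loc[genes["gene_class"].isin(["b_linked_UC", "b_linked_IC"]), "contig_id"]
    )
    universe = set(genes["contig_id"])
    candidate_score = synth.score_recovery(candidates, truth_contigs, universe)
    truth_snps = {
        (r.contig_id, r.position)
        for r in ds.manifest.snps.itertuples(index=False)
        if r.contig_id in candidates
    }
    called = {(c.contig_id, c.position) for c in snp_calls if c.verdict == "PASS"}
    snp_score = synth.score_recovery(called, truth_snps)
    recovery = {"candidates": candidate_score, "snps": snp_score}

    manifest = RunManifest(
        seed=seed,
        config={"simulate": dataclasses.asdict(sim_cfg),
                "selection": dataclasses.asdict(sel_cfg),
                "snp": dataclasses.asdict(snp_cfg)},
        summary={
            "n_contigs": len(universe),
            "n_pass_copy_filter": len(kept),
            "n_candidates": len(candidates),
            "n_pass_snps": len(called),
            "recovery": recovery,
        },
    )

    result = PipelineResult(
        manifest=manifest,
        dataset=ds,
        copy_table=copy_table,
        gfc_records=gfc_records,
        candidates=candidates,
        segments=segments,
        snp_calls=snp_calls,
        expression=expression_df,
        qpcr_validation=qpcr_validation,
        recovery=recovery,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    ds = result.dataset
    files = {}

    p = out / "copy_number.tsv"
    result.copy_table.to_csv(p, sep="\t", index=False)
    files["copy_number"] = p

    p = out / "gfc.tsv"
    sel.gfc_table(result.gfc_records).to_csv(p, sep="\t", index=False)
    files["gfc"] = p

    p = out / "segments.bed"
    all_segs = [s for segs, _ in result.segments.values() for s in segs]
    write_segments_bed(all_segs, p)
    files["segments"] = p

    p = out / "snps.vcf"
    write_snp_vcf(result.snp_calls, ds.contig_lengths, p)
    files["snps"] = p

    p = out / "expression.tsv"
    result.expression.to_csv(p, sep="\t", index=False)
    files["expression"] = p

    p = out / "qpcr_validation.tsv"
    result.qpcr_validation.to_csv(p, sep="\t", index=False)
    files["qpcr_validation"] = p

    p = out / "recovery.json"
    p.write_text(json.dumps(result.recovery, indent=2, sort_keys=True))
    files["recovery"] = p

    for name, path in files.items():
        result.manifest.outputs[name] = str(path)
        result.manifest.checksums[name] = _sha256(path)
    (out / "run_manifest.json").write_text(
        json.dumps(dataclasses.asdict(result.manifest), indent=2, sort_keys=True,
                   default=str)
    )
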