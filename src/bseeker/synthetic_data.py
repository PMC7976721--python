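"""Seeded synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the study design at the depth/pileup level (no reads,
no alignment): a focal species with three B-lacking and three B-carrying
gDNA libraries plus ovary RNA libraries, and a sister species with a single
0B/1B pair.  Per-position gDNA depth is Poisson with mean
``copies_per_cell × L/G`` (``L`` = library bases, ``G`` = genome size), so
the copy-number estimator is exactly calibrated.  Gene classes:

- ``single_copy`` — one copy per haploid A genome, no B copy;
- ``b_linked_UC`` — ``b_copies`` extra copies on the B along the whole
  contig (uniform coverage);
- ``b_linked_IC`` — ``ic_b_copies`` extra copies over only the 5' part of
  the contig (irregular coverage, HC/LC structure);
- ``repetitive`` — many copies per haploid (copy filter should discard);
- ``low_copy`` — < 0.5 copies per haploid (copy filter should discard).

B paralogs carry exclusive Alt alleles at planted SNP positions; the Alt
fraction of 1B gDNA is ``b/(2+b)`` for ``b`` B copies.  RNA pileups plant
allele fractions set by each gene's B:A transcription ratio, and Ct tables
encode copy-number and expression ratios as ΔCt = -log2(ratio) plus
Gaussian noise.  Every planted signal is recorded in a ground-truth
manifest sufficient to score recovery exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .copy_number import GenomeModel
from .io_formats import (
    ALLELES,
    ALLELE_INDEX,
    ContigRecord,
    DepthTrack,
    LibraryInfo,
    PileupCounts,
    write_contigs_tsv,
    write_depth_tsv,
    write_fasta,
    write_libraries_tsv,
    write_pileup_tsv,
)
from .qpcr_stats import CtRecord

GENE_CLASSES = ("single_copy", "b_linked_UC", "b_linked_IC", "repetitive", "low_copy")
BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # focal species replicate structure (3 0B + 3 1B gDNA; 2 + 2 ovary RNA)
    n_0B: int = 3
    n_1B: int = 3
    n_rna_0B: int = 2
    n_rna_1B: int = 2
    # sister species: single 0B/1B pair
    cross_n_0B: int = 1
    n_genes: int = 230
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "single_copy": 200 / 230,
            "b_linked_UC": 14 / 230,
            "b_linked_IC": 6 / 230,
            "repetitive": 5 / 230,
            "low_copy": 5 / 230,
        }
    )
    contig_length: int = 1000
    cds_start: int = 101  # 1-based inclusive
    cds_end: int = 900
    b_copies: int = 2
    ic_b_copies: int = 4
    ic_hc_fraction: float = 0.5
    repetitive_copies: float = 6.0  # per haploid genome
    low_copy_copies: float = 0.3
    depth_factor: float = 20.0  # L/G per gDNA library
    rna_depth: float = 200.0  # mean RNA depth per CDS position, per library
    snp_rate: float = 0.01  # planted B-exclusive variants per CDS nt
    indel_fraction: float = 0.1  # of planted variants; split between ins and del
    expression_ratio: float = 1.0  # B:A transcription of UC B-linked genes
    ct_noise_sd: float = 0.2
    seq_error_alt_rate: float = 0.0
    overdispersion: float = 1.0
    genome_diploid_pg: float = 3.74
    b_fraction_of_haploid: float = 0.05

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be non-negative")
        if not (self.snp_rate >= 0 and self.rna_depth >= 0 and self.depth_factor > 0):
            raise ValueError("rates must be non-negative, depth_factor positive")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")

    def class_counts(self) -> dict[str, int]:
        counts = {
            cls: int(round(self.class_fractions.get(cls, 0.0) * self.n_genes))
            for cls in GENE_CLASSES
        }
        counts["single_copy"] += self.n_genes - sum(counts.values())
        return counts

    def genome_model(self) -> GenomeModel:
        return GenomeModel(
            diploid_size_pg=self.genome_diploid_pg,
            b_fraction_of_haploid=self.b_fraction_of_haploid,
        )


@dataclass
class GroundTruthManifest:
    genes: pd.DataFrame      # per-gene class, true copies, breakpoints, ratios
    snps: pd.DataFrame       # planted B-exclusive variants with allele fractions
    libraries: pd.DataFrame  # genotype and library size per library


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    libraries: list[LibraryInfo]          # focal species (gDNA + RNA)
    cross_libraries: list[LibraryInfo]    # sister-species 0B libraries
    contigs: list[ContigRecord]
    sequences: dict[str, str]
    depth_tracks: dict[tuple[str, str], DepthTrack]      # (library_id, contig_id)
    group_pileups: dict[str, dict[str, PileupCounts]]    # contig -> group -> pileup
    rna_pileups: dict[str, dict[str, PileupCounts]]      # contig -> rna library -> pileup
    cross_pileups: dict[str, list[PileupCounts]]         # contig -> per cross library
    ct_gdna: list[CtRecord]
    ct_rna: list[CtRecord]
    manifest: GroundTruthManifest

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c.contig_id: c.length for c in self.contigs}


def _poisson(rng: np.random.Generator, mean: np.ndarray, overdispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if overdispersion <= 1.0:
        return rng.poisson(mean)
    # gamma-Poisson mixture with variance = overdispersion * mean
    extra = overdispersion - 1.0
    shape = np.where(mean > 0, mean / extra, 1.0)
    lam = np.where(mean > 0, rng.gamma(shape, extra), 0.0)
    return rng.poisson(lam)


def simulate_ct_records(
    gene: str,
    rq_0B: float,
    rq_1B: float,
    n_0B: int,
    n_1B: int,
    noise_sd: float,
    rng: np.random.Generator,
    n_reps: int = 3,
    baseline_ct: float = 20.0,
) -> list[CtRecord]:
    """Ct wells for one gene: ΔCt = -log2(ratio) + Gaussian noise per well."""
    records = []
    for group, n, rq in (("0B", n_0B, rq_0B), ("1B", n_1B, rq_1B)):
        for ind in range(1, n + 1):
            for rep in range(1, n_reps + 1):
                ct_ref = baseline_ct + rng.normal(0.0, noise_sd)
                ct_tgt = baseline_ct - math.log2(rq) + rng.normal(0.0, noise_sd)
                records.append(
                    CtRecord(
                        sample_id=f"{group}_{ind}",
                        group=group,
                        target_gene=gene,
                        ct_target=ct_tgt,
                        ct_reference=ct_ref,
                        replicate_id=rep,
                    )
                )
    return records


def _gene_table(cfg: SimulationConfig) -> pd.DataFrame:
    counts = cfg.class_counts()
    rows = []
    idx = 0
    hc_len = int(round(cfg.contig_length * cfg.ic_hc_fraction))
    for cls in GENE_CLASSES:
        for _ in range(counts[cls]):
            idx += 1
            gene = f"g{idx:04d}"
            copies_0B = {
                "single_copy": 1.0,
                "b_linked_UC": 1.0,
                "b_linked_IC": 1.0,
                "repetitive": cfg.repetitive_copies,
                "low_copy": cfg.low_copy_copies,
            }[cls]
            b_extra = {"b_linked_UC": cfg.b_copies, "b_linked_IC": cfg.ic_b_copies}.get(cls, 0)
            hc_start, hc_end = (0, hc_len) if cls == "b_linked_IC" else (0, cfg.contig_length)
            # CDS-mean copies per haploid in a 1B individual
            cds0, cds1 = cfg.cds_start - 1, cfg.cds_end
            overlap = max(0, min(hc_end, cds1) - max(hc_start, cds0))
            frac_cds = overlap / (cds1 - cds0)
            copies_1B = copies_0B + b_extra * frac_cds / 2.0
            expr = cfg.expression_ratio if cls == "b_linked_UC" else 0.0
            rows.append(
                {
                    "gene": gene,
                    "contig_id": f"c{idx:04d}",
                    "gene_class": cls,
                    "copies_0B_per_haploid": copies_0B,
                    "copies_1B_per_haploid": copies_1B,
                    "b_extra_copies": b_extra,
                    "hc_start": hc_start,
                    "hc_end": hc_end,
                    "expected_gfc": math.log2(copies_1B / copies_0B),
                    "expression_ratio": expr,
                }
            )
    return pd.DataFrame(rows)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate a complete dataset bundle plus its ground-truth manifest."""
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_table(cfg)
    model = cfg.genome_model()
    g0 = model.with_b_count(0).size_bases
    g1 = model.with_b_count(1).size_bases

    # --- libraries ----------------------------------------------------------
    libraries: list[LibraryInfo] = []
    for i in range(1, cfg.n_0B + 1):
        libraries.append(LibraryInfo(f"gdna_0B_{i}", "focal", f"F0_{i}", "muscle",
                                     "gDNA", 0, int(round(cfg.depth_factor * g0))))
    for i in range(1, cfg.n_1B + 1):
        libraries.append(LibraryInfo(f"gdna_1B_{i}", "focal", f"F1_{i}", "muscle",
                                     "gDNA", 1, int(round(cfg.depth_factor * g1))))
    rna_ids_0B = [f"rna_0B_{i}" for i in range(1, cfg.n_rna_0B + 1)]
    rna_ids_1B = [f"rna_1B_{i}" for i in range(1, cfg.n_rna_1B + 1)]
    rna_bases = int(round(cfg.rna_depth * cfg.n_genes * cfg.contig_length))
    for i, lid in enumerate(rna_ids_0B, start=1):
        libraries.append(LibraryInfo(lid, "focal", f"F0_{i}", "ovary", "RNA", 0, rna_bases))
    for i, lid in enumerate(rna_ids_1B, start=1):
        libraries.append(LibraryInfo(lid, "focal", f"F1_{i}", "ovary", "RNA", 1, rna_bases))
    cross_libraries = []
    for i in range(1, cfg.cross_n_0B + 1):
        cross_libraries.append(LibraryInfo(f"xs_gdna_0B_{i}", "sister", f"S0_{i}", "muscle",
                                           "gDNA", 0, int(round(cfg.depth_factor * g0))))
        cross_libraries.append(LibraryInfo(f"xs_rna_0B_{i}", "sister", f"S0_{i}", "ovary",
                                           "RNA", 0, rna_bases))

    # --- contigs and sequences ---------------------------------------------
    contigs: list[ContigRecord] = []
    sequences: dict[str, str] = {}
    annot = {"repetitive": "repetitive"}
    base_arr = np.array(list("ACGT"))
    for row in genes.itertuples(index=False):
        contigs.append(
            ContigRecord(
                contig_id=row.contig_id,
                length=cfg.contig_length,
                cds_start=cfg.cds_start,
                cds_end=cfg.cds_end,
                gene_name=row.gene,
                annotation_class=annot.get(row.gene_class, "protein_coding"),
            )
        )
        sequences[row.contig_id] = "".join(
            base_arr[rng.integers(0, 4, size=cfg.contig_length)]
        )

    # --- planted B-exclusive variants ---------------------------------------
    snp_rows = []
    for row in genes.itertuples(index=False):
        if row.b_extra_copies == 0 or cfg.snp_rate == 0:
            continue
        cds0, cds1 = cfg.cds_start - 1, cfg.cds_end
        lo, hi = max(cds0, row.hc_start), min(cds1, row.hc_end)
        seq = sequences[row.contig_id]
        positions = np.nonzero(rng.random(hi - lo) < cfg.snp_rate)[0] + lo
        b = row.b_extra_copies
        alt_frac_gdna = b / (2.0 + b)
        r = row.expression_ratio
        alt_frac_rna = r / (1.0 + r) if r > 0 else 0.0
        for pos in positions:
            ref = seq[pos]
            u = rng.random()
            if u < cfg.indel_fraction / 2:
                alt = "ins"
            elif u < cfg.indel_fraction:
                alt = "del"
            else:
                alt = str(rng.choice([b_ for b_ in BASES if b_ != ref]))
            snp_rows.append(
                {
                    "contig_id": row.contig_id,
                    "gene": row.gene,
                    "position": int(pos) + 1,
                    "ref": ref,
                    "alt": alt,
                    "alt_frac_gdna_1B": alt_frac_gdna,
                    "alt_frac_rna_1B": alt_frac_rna,
                }
            )
    snps = pd.DataFrame(
        snp_rows,
        columns=["contig_id", "gene", "position", "ref", "alt",
                 "alt_frac_gdna_1B", "alt_frac_rna_1B"],
    )

    # --- depth tracks and pileups -------------------------------------------
    depth_tracks: dict[tuple[str, str], DepthTrack] = {}
    group_pileups: dict[str, dict[str, PileupCounts]] = {}
    rna_pileups: dict[str, dict[str, PileupCounts]] = {}
    cross_pileups: dict[str, list[PileupCounts]] = {}
    n = cfg.contig_length
    cds0, cds1 = cfg.cds_start - 1, cfg.cds_end

    base_code = np.zeros(256, dtype=np.int64)
    for i, b_ in enumerate(BASES):
        base_code[ord(b_)] = ALLELE_INDEX[b_]

    def pileup_from_depth(
        seq: str, depth: np.ndarray, snp_sub: pd.DataFrame, frac_col: str | None,
        group_id: str, contig_id: str, err_rate: float,
    ) -> PileupCounts:
        counts = np.zeros((n, len(ALLELES)), dtype=np.int64)
        ridx = base_code[np.frombuffer(seq.encode(), dtype=np.uint8)]
        counts[np.arange(n), ridx] = depth
        if frac_col is not None:
            for s in snp_sub.itertuples(index=False):
                i = s.position - 1
                frac = getattr(s, frac_col)
                if frac <= 0 or depth[i] == 0:
                    continue
                a = rng.binomial(depth[i], frac)
                counts[i, ALLELE_INDEX[s.alt]] += a
                counts[i, ridx[i]] -= a
        if err_rate > 0:
            errs = rng.binomial(depth, err_rate)
            for i in np.nonzero(errs)[0]:
                e = min(int(errs[i]), int(counts[i, ridx[i]]))
                if e == 0:
                    continue
                wrong = (ridx[i] + rng.integers(1, 4)) % 4
                counts[i, wrong] += e
                counts[i, ridx[i]] -= e
        return PileupCounts(group_id=group_id, contig_id=contig_id, counts=counts)

    for row in genes.itertuples(index=False):
        contig = row.contig_id
        seq = sequences[contig]
        snp_sub = snps[snps["contig_id"] == contig] if not snps.empty else snps
        # per-cell copy profiles along the contig
        copies_0B_cell = np.full(n, 2.0 * row.copies_0B_per_haploid)
        copies_1B_cell = copies_0B_cell.copy()
        if row.b_extra_copies > 0:
            copies_1B_cell[row.hc_start:row.hc_end] += row.b_extra_copies

        for lib in libraries:
            if lib.molecule != "gDNA":
                continue
            prof = copies_1B_cell if lib.b_count == 1 else copies_0B_cell
            depth = _poisson(rng, prof * cfg.depth_factor, cfg.overdispersion)
            depth_tracks[(lib.library_id, contig)] = DepthTrack(lib.library_id, contig, depth)

        # merged group pileups: sums of independent Poissons are Poisson
        d0 = _poisson(rng, copies_0B_cell * cfg.depth_factor * cfg.n_0B, cfg.overdispersion)
        d1 = _poisson(rng, copies_1B_cell * cfg.depth_factor * cfg.n_1B, cfg.overdispersion)
        gp = {
            "gDNA_0B": pileup_from_depth(seq, d0, snp_sub, None, "gDNA_0B", contig,
                                         cfg.seq_error_alt_rate),
            "gDNA_1B": pileup_from_depth(seq, d1, snp_sub, "alt_frac_gdna_1B", "gDNA_1B",
                                         contig, cfg.seq_error_alt_rate),
        }
        # RNA: A paralogs of protein-coding genes expressed over the CDS
        rna_mean = np.zeros(n)
        if row.gene_class != "repetitive":
            rna_mean[cds0:cds1] = cfg.rna_depth
        r = row.expression_ratio
        rna_mean_1B = rna_mean * (1.0 + r)
        per_lib: dict[str, PileupCounts] = {}
        for lid in rna_ids_0B:
            d = _poisson(rng, rna_mean, cfg.overdispersion)
            per_lib[lid] = pileup_from_depth(seq, d, snp_sub, None, lid, contig, 0.0)
        for lid in rna_ids_1B:
            d = _poisson(rng, rna_mean_1B, cfg.overdispersion)
            per_lib[lid] = pileup_from_depth(seq, d, snp_sub, "alt_frac_rna_1B", lid,
                                             contig, 0.0)
        rna_pileups[contig] = per_lib
        gp["RNA_0B"] = PileupCounts(
            "RNA_0B", contig, sum(per_lib[l].counts for l in rna_ids_0B)
        )
        gp["RNA_1B"] = PileupCounts(
            "RNA_1B", contig, sum(per_lib[l].counts for l in rna_ids_1B)
        )
        group_pileups[contig] = gp

        xs = []
        for lib in cross_libraries:
            mean = (copies_0B_cell * cfg.depth_factor) if lib.molecule == "gDNA" else rna_mean
            d = _poisson(rng, mean, cfg.overdispersion)
            xs.append(pileup_from_depth(seq, d, snp_sub, None, lib.library_id, contig,
                                        cfg.seq_error_alt_rate))
        cross_pileups[contig] = xs

    # --- qPCR Ct tables -------------------------------------------------------
    ct_gdna: list[CtRecord] = []
    ct_rna: list[CtRecord] = []
    panel = genes[genes["gene_class"].isin(["b_linked_UC", "b_linked_IC"])]
    controls = genes[genes["gene_class"] == "single_copy"].head(5)
    for row in pd.concat([panel, controls]).itertuples(index=False):
        # primers sit in the HC region of IC genes, so RQ sees the full B dose
        rq_1B = (2.0 * row.copies_0B_per_haploid + row.b_extra_copies) / (
            2.0 * row.copies_0B_per_haploid
        )
        ct_gdna.extend(
            simulate_ct_records(row.gene, 1.0, rq_1B, cfg.n_0B, cfg.n_1B,
                                cfg.ct_noise_sd, rng, n_reps=3)
        )
    for row in panel.itertuples(index=False):
        fold = 1.0 + row.expression_ratio
        ct_rna.extend(
            simulate_ct_records(row.gene, 1.0, fold, cfg.n_rna_0B, cfg.n_rna_1B,
                                cfg.ct_noise_sd, rng, n_reps=2)
        )

    lib_rows = [
        {
            "library_id": l.library_id, "species": l.species, "molecule": l.molecule,
            "b_count": l.b_count, "total_bases": l.total_bases,
        }
        for l in libraries + cross_libraries
    ]
    manifest = GroundTruthManifest(
        genes=genes, snps=snps, libraries=pd.DataFrame(lib_rows)
    )
    return SimulatedDataset(
        config=cfg,
        libraries=libraries,
        cross_libraries=cross_libraries,
        contigs=contigs,
        sequences=sequences,
        depth_tracks=depth_tracks,
        group_pileups=group_pileups,
        rna_pileups=rna_pileups,
        cross_pileups=cross_pileups,
        ct_gdna=ct_gdna,
        ct_rna=ct_rna,
        manifest=manifest,
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, str]:
    """Write the bundle as plain-text files readable by the io_formats module."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    write_fasta(ds.sequences, out / "contigs.fasta")
    write_contigs_tsv(ds.contigs, out / "contigs.tsv")
    write_libraries_tsv(ds.libraries + ds.cross_libraries, out / "libraries.tsv")
    paths.update(contigs_fasta="contigs.fasta", contigs_tsv="contigs.tsv",
                 libraries="libraries.tsv")

    depth_dir = out / "depth"
    depth_dir.mkdir(exist_ok=True)
    by_lib: dict[str, list[DepthTrack]] = {}
    for (lib_id, _), track in ds.depth_tracks.items():
        by_lib.setdefault(lib_id, []).append(track)
    for lib_id, tracks in by_lib.items():
        write_depth_tsv(sorted(tracks, key=lambda t: t.contig_id),
                        depth_dir / f"{lib_id}.depth.tsv")

    pile_dir = out / "pileup"
    pile_dir.mkdir(exist_ok=True)
    groups = sorted({g for gp in ds.group_pileups.values() for g in gp})
    for group in groups:
        piles = [ds.group_pileups[c][group] for c in sorted(ds.group_pileups)]
        write_pileup_tsv(piles, pile_dir / f"{group}.pileup.tsv")
    rna_lib_ids = sorted({l for d in ds.rna_pileups.values() for l in d})
    for lid in rna_lib_ids:
        piles = [ds.rna_pileups[c][lid] for c in sorted(ds.rna_pileups)]
        write_pileup_tsv(piles, pile_dir / f"{lid}.pileup.tsv")
    xs_ids = [l.library_id for l in ds.cross_libraries]
    for i, lid in enumerate(xs_ids):
        piles = [ds.cross_pileups[c][i] for c in sorted(ds.cross_pileups)]
        write_pileup_tsv(piles, pile_dir / f"{lid}.pileup.tsv")

    ct_rows = [
        {
            "sample_id": r.sample_id, "group": r.group, "target_gene": r.target_gene,
            "ct_target": r.ct_target, "ct_reference": r.ct_reference,
            "replicate_id": r.replicate_id,
        }
        for r in ds.ct_gdna
    ]
    pd.DataFrame(ct_rows).to_csv(out / "ct_gdna.tsv", sep="\t", index=False)
    ct_rows = [
        {
            "sample_id": r.sample_id, "group": r.group, "target_gene": r.target_gene,
            "ct_target": r.ct_target, "ct_reference": r.ct_reference,
            "replicate_id": r.replicate_id,
        }
        for r in ds.ct_rna
    ]
    pd.DataFrame(ct_rows).to_csv(out / "ct_rna.tsv", sep="\t", index=False)

    truth = out / "truth"
    truth.mkdir(exist_ok=True)
    ds.manifest.genes.to_csv(truth / "genes.tsv", sep="\t", index=False)
    ds.manifest.snps.to_csv(truth / "snps.tsv", sep="\t", index=False)
    ds.manifest.libraries.to_csv(truth / "libraries.tsv", sep="\t", index=False)
    return paths


def score_recovery(
    predicted: set, truth: set, universe: set | None = None
) -> dict[str, float]:
    """Confusion counts and precision/recall of a predicted label set."""
    predicted, truth = set(predicted), set(truth)
    if universe is not None:
        universe = set(universe)
        unknown = (predicted | truth) - universe
        if unknown:
            raise ValueError(f"labels outside the scoring universe: {sorted(unknown)[:5]}")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    out = {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
        "recall": tp / (tp + fn) if (tp + fn) else float("nan"),
    }
    if universe is not None:
        tn = len(universe) - tp - fp - fn
        out["tn"] = tn
        out["specificity"] = tn / (tn + fp) if (tn + fp) else float("nan")
    return out
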