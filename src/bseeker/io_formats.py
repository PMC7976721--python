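"""On-disk dialects shared by every pipeline stage.

All files use 1-based inclusive coordinates; in memory everything is
0-based half-open.  The conversion happens exactly once, here.  Depth and
pileup files are sparse: a position absent from the file has depth (or
counts) zero, mirroring the behaviour of common depth emitters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Allele order used everywhere (pileup columns, tie-breaking).
ALLELES = ("A", "C", "G", "T", "ins", "del")
ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}

MOLECULES = ("gDNA", "RNA")
ANNOTATION_CLASSES = ("protein_coding", "repetitive", "unannotated")


class ParseError(ValueError):
    """Raised for malformed input files; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True)
class LibraryInfo:
    """One sequencing library and the metadata the pipeline needs.

    ``total_bases`` is the summed length of all sequenced reads; it is the
    library-size term of the copy-number conversion.  ``molecule`` gates
    which stages may consume the library: copy number uses gDNA only,
    expression uses RNA only.
    """

    library_id: str
    species: str
    individual_id: str
    tissue: str
    molecule: str
    b_count: int
    total_bases: int

    def __post_init__(self):
        if self.molecule not in MOLECULES:
            raise ValueError(f"molecule must be one of {MOLECULES}, got {self.molecule!r}")
        if self.b_count not in (0, 1):
            raise ValueError(f"b_count must be 0 or 1, got {self.b_count}")
        if self.total_bases <= 0:
            raise ValueError("total_bases must be positive")


@dataclass(frozen=True)
class ContigRecord:
    """A reference transcriptome contig with its CDS coordinates (1-based inclusive)."""

    contig_id: str
    length: int
    cds_start: int
    cds_end: int
    gene_name: str | None = None
    annotation_class: str = "protein_coding"

    def __post_init__(self):
        if not (1 <= self.cds_start <= self.cds_end <= self.length):
            raise ValueError(
                f"{self.contig_id}: require 1 <= cds_start <= cds_end <= length, "
                f"got cds=[{self.cds_start},{self.cds_end}] length={self.length}"
            )
        if self.annotation_class not in ANNOTATION_CLASSES:
            raise ValueError(f"unknown annotation_class {self.annotation_class!r}")

    @property
    def cds_interval(self) -> tuple[int, int]:
        """CDS as a 0-based half-open interval."""
        return self.cds_start - 1, self.cds_end


@dataclass
class DepthTrack:
    """Per-position read depth of one library on one contig."""

    library_id: str
    contig_id: str
    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D array")
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")


@dataclass
class PileupCounts:
    """Per-position allele counts (A, C, G, T, ins, del) for one group or library."""

    group_id: str
    contig_id: str
    counts: np.ndarray  # shape (length, 6), columns in ALLELES order

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(ALLELES):
            raise ValueError(f"counts must have shape (length, {len(ALLELES)})")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def length(self) -> int:
        return self.counts.shape[0]


# ---------------------------------------------------------------------------
# depth TSV (contig_id, position, depth) — SAM-style depth dialect
# ---------------------------------------------------------------------------

def read_depth_tsv(
    path, contig_lengths: Mapping[str, int], library_id: str
) -> list[DepthTrack]:
    """Read a three-column depth file into one DepthTrack per contig.

    Positions absent from the file get depth 0; every contig listed in
    ``contig_lengths`` yields a track, even if entirely uncovered.
    """
    arrays = {c: np.zeros(n, dtype=np.int64) for c, n in contig_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(path, lineno, f"expected 3 tab-separated fields, got {len(parts)}")
            contig, pos_s, depth_s = parts
            if contig not in arrays:
                raise ParseError(path, lineno, f"unknown contig {contig!r}")
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer field: {exc}") from None
            if not (1 <= pos <= contig_lengths[contig]):
                raise ParseError(
                    path, lineno,
                    f"position {pos} outside contig {contig} (length {contig_lengths[contig]})",
                )
            if depth < 0:
                raise ParseError(path, lineno, f"negative depth {depth}")
            arrays[contig][pos - 1] = depth
    return [
        DepthTrack(library_id=library_id, contig_id=c, depth=arr)
        for c, arr in arrays.items()
    ]


def write_depth_tsv(tracks: Iterable[DepthTrack], path) -> None:
    """Write depth tracks in the sparse three-column dialect (zeros omitted)."""
    with open(path, "w") as fh:
        for track in tracks:
            (nz,) = np.nonzero(track.depth)
            for i in nz:
                fh.write(f"{track.contig_id}\t{i + 1}\t{track.depth[i]}\n")


# ---------------------------------------------------------------------------
# pileup TSV (contig_id, position, countA..countDel)
# ---------------------------------------------------------------------------

def read_pileup_tsv(
    path, contig_lengths: Mapping[str, int], group_id: str
) -> list[PileupCounts]:
    """Read an eight-column pileup count file; missing positions are all-zero."""
    arrays = {
        c: np.zeros((n, len(ALLELES)), dtype=np.int64) for c, n in contig_lengths.items()
    }
    ncol = 2 + len(ALLELES)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != ncol:
                raise ParseError(path, lineno, f"expected {ncol} fields, got {len(parts)}")
            contig = parts[0]
            if contig not in arrays:
                raise ParseError(path, lineno, f"unknown contig {contig!r}")
            try:
                pos = int(parts[1])
                counts = [int(x) for x in parts[2:]]
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer field: {exc}") from None
            if not (1 <= pos <= contig_lengths[contig]):
                raise ParseError(path, lineno, f"position {pos} outside contig {contig}")
            if any(c < 0 for c in counts):
                raise ParseError(path, lineno, "negative count")
            arrays[contig][pos - 1, :] = counts
    return [
        PileupCounts(group_id=group_id, contig_id=c, counts=arr)
        for c, arr in arrays.items()
    ]


def write_pileup_tsv(pileups: Iterable[PileupCounts], path) -> None:
    """Write pileup counts, omitting all-zero positions."""
    with open(path, "w") as fh:
        for p in pileups:
            covered = np.nonzero(p.counts.any(axis=1))[0]
            for i in covered:
                fields = "\t".join(str(x) for x in p.counts[i])
                fh.write(f"{p.contig_id}\t{i + 1}\t{fields}\n")


# ---------------------------------------------------------------------------
# VCF 4.2 for B-specific variant calls
# ---------------------------------------------------------------------------

#: INFO keys for per-group Ref/Alt counts, in fixed order.
_VCF_GROUPS = ("GD0", "GD1", "RN0", "RN1")
_VCF_INFO_HEADER = [
    ('GD0_REF', 'Ref-allele count in merged 0B gDNA'),
    ('GD0_ALT', 'Alt-allele count in merged 0B gDNA'),
    ('GD1_REF', 'Ref-allele count in merged 1B gDNA'),
    ('GD1_ALT', 'Alt-allele count in merged 1B gDNA'),
    ('RN0_REF', 'Ref-allele count in merged 0B RNA'),
    ('RN0_ALT', 'Alt-allele count in merged 0B RNA'),
    ('RN1_REF', 'Ref-allele count in merged 1B RNA'),
    ('RN1_ALT', 'Alt-allele count in merged 1B RNA'),
    ('XS_ALT', 'Maximum Alt-allele count over cross-species 0B libraries'),
    ('EVENT', 'Mutational event id (adjacent same-type indels share one)'),
    ('ALTK', 'Alt allele kind: sub, ins or del'),
]


def _vcf_alleles(call) -> tuple[str, str]:
    ref = call.ref_allele
    alt = call.alt_allele
    if alt == "ins":
        return ref, "<INS>"
    if alt == "del":
        return ref, "<DEL>"
    return ref, alt


def write_snp_vcf(calls: Sequence, contig_lengths: Mapping[str, int], path) -> None:
    """Write calls as minimal VCF 4.2.

    Substitutions use literal REF/ALT bases; insertion and deletion calls use
    the symbolic alleles <INS> and <DEL> with the allele kind repeated in the
    ALTK INFO field so a read-back is lossless.
    """
    lines = ["##fileformat=VCFv4.2"]
    for contig, length in sorted(contig_lengths.items()):
        lines.append(f"##contig=<ID={contig},length={length}>")
    for key, desc in _VCF_INFO_HEADER:
        typ = "String" if key == "ALTK" else "Integer"
        lines.append(f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">')
    verdicts = sorted({c.verdict for c in calls} - {"PASS"})
    for v in verdicts:
        lines.append(f'##FILTER=<ID={v},Description="Failed filter {v}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    ordered = sorted(calls, key=lambda c: (c.contig_id, c.position, c.alt_allele))
    for call in ordered:
        ref, alt = _vcf_alleles(call)
        info_parts = []
        for tag, group in zip(_VCF_GROUPS, ("gDNA_0B", "gDNA_1B", "RNA_0B", "RNA_1B")):
            r, a = call.group_counts.get(group, (0, 0))
            info_parts.append(f"{tag}_REF={r}")
            info_parts.append(f"{tag}_ALT={a}")
        info_parts.append(f"XS_ALT={call.cross_species_alt}")
        info_parts.append(f"EVENT={-1 if call.event_id is None else call.event_id}")
        kind = "sub" if call.alt_allele in "ACGT" else call.alt_allele
        info_parts.append(f"ALTK={kind}")
        lines.append(
            f"{call.contig_id}\t{call.position}\t.\t{ref}\t{alt}\t.\t"
            f"{call.verdict}\t{';'.join(info_parts)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_snp_vcf(path) -> list:
    """Read back a VCF written by :func:`write_snp_vcf` (uses pysam)."""
    import pysam

    from .snp_calling import SnpCall  # local import: avoid cycle

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            kind = info["ALTK"]
            alt = rec.alts[0] if rec.alts else "."
            alt_allele = kind if kind in ("ins", "del") else alt
            group_counts = {}
            for tag, group in zip(_VCF_GROUPS, ("gDNA_0B", "gDNA_1B", "RNA_0B", "RNA_1B")):
                group_counts[group] = (int(info[f"{tag}_REF"]), int(info[f"{tag}_ALT"]))
            filt = list(rec.filter.keys())
            event = int(info["EVENT"])
            calls.append(
                SnpCall(
                    contig_id=rec.chrom,
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alt_allele,
                    group_counts=group_counts,
                    cross_species_alt=int(info["XS_ALT"]),
                    verdict=filt[0] if filt else "PASS",
                    event_id=None if event < 0 else event,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# BED (0-based half-open) for HC/LC segments
# ---------------------------------------------------------------------------

def write_segments_bed(segments: Iterable, path) -> None:
    """Write HC/LC segments as BED4 (+ mean log2 ratio in column 5)."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{seg.contig_id}\t{seg.start}\t{seg.end}\t{seg.label}\t{seg.mean_ratio:.6g}\n"
            )


# ---------------------------------------------------------------------------
# FASTA / tables / config
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=contig, description="") for contig, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_contigs_tsv(contigs: Iterable[ContigRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tlength\tcds_start\tcds_end\tgene_name\tannotation_class\n")
        for c in contigs:
            fh.write(
                f"{c.contig_id}\t{c.length}\t{c.cds_start}\t{c.cds_end}\t"
                f"{c.gene_name or ''}\t{c.annotation_class}\n"
            )


def read_contigs_tsv(path) -> list[ContigRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene_name": "string"})
    out = []
    for row in df.itertuples(index=False):
        gene = None if (row.gene_name is None or row.gene_name != row.gene_name) else str(row.gene_name)
        out.append(
            ContigRecord(
                contig_id=str(row.contig_id),
                length=int(row.length),
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                gene_name=gene or None,
                annotation_class=str(row.annotation_class),
            )
        )
    return out


def write_libraries_tsv(libraries: Iterable[LibraryInfo], path) -> None:
    with open(path, "w") as fh:
        fh.write("library_id\tspecies\tindividual_id\ttissue\tmolecule\tb_count\ttotal_bases\n")
        for lib in libraries:
            fh.write(
                f"{lib.library_id}\t{lib.species}\t{lib.individual_id}\t{lib.tissue}\t"
                f"{lib.molecule}\t{lib.b_count}\t{lib.total_bases}\n"
            )


def read_libraries_tsv(path) -> list[LibraryInfo]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        LibraryInfo(
            library_id=str(r.library_id),
            species=str(r.species),
            individual_id=str(r.individual_id),
            tissue=str(r.tissue),
            molecule=str(r.molecule),
            b_count=int(r.b_count),
            total_bases=int(r.total_bases),
        )
        for r in df.itertuples(index=False)
    ]


def load_config(path) -> dict:
    """Load a YAML run configuration (thresholds, groups, simulation block)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
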