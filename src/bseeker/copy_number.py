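"""Read depth → copies per haploid genome.

A diploid individual contributes reads from both homologs onto the single
haploid reference coordinate, so a locus present once per haploid genome
(twice per cell) has expected depth ``2 L / G`` for a library of ``L``
sequenced bases and a genome of ``G`` bases.  Inverting,

    copies_per_haploid = mean_depth * G / (2 * L)

which makes a single-copy gene 1.0 and a gene with one extra B-chromosome
copy in a 1B individual 3/2 = 1.5, the ratio behind the log2(1.5) genomic
fold-change threshold.  B-carrying genomes use a B-adjusted ``G``: the B
adds a fixed fraction of the haploid A-genome size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import ContigRecord, DepthTrack, LibraryInfo

#: 1 pg of DNA corresponds to 0.978 Gb.
PG_TO_GB = 0.978


@dataclass(frozen=True)
class GenomeModel:
    """Genome size model for a species, with B-chromosome adjustment.

    Parameters
    ----------
    diploid_size_pg
        Flow-cytometric diploid (0B) genome size in picograms.
    b_fraction_of_haploid
        Size of one B chromosome as a fraction of the haploid A-chromosome
        complement (default 0.05, i.e. ~5 % of A chromosomes).
    pg_to_gb
        Conversion constant, Gb per pg.
    b_count
        Number of B chromosomes carried (0 or 1 in this design).
    """

    diploid_size_pg: float
    b_fraction_of_haploid: float = 0.05
    pg_to_gb: float = PG_TO_GB
    b_count: int = 0

    def __post_init__(self):
        if self.diploid_size_pg <= 0:
            raise ValueError("diploid_size_pg must be positive")
        if not (0 <= self.b_fraction_of_haploid < 1):
            raise ValueError("b_fraction_of_haploid must be in [0, 1)")
        if self.pg_to_gb <= 0:
            raise ValueError("pg_to_gb must be positive")
        if self.b_count < 0:
            raise ValueError("b_count must be non-negative")

    def with_b_count(self, b_count: int) -> "GenomeModel":
        return replace(self, b_count=b_count)

    @property
    def size_pg(self) -> float:
        """Effective genome size in pg, including carried B chromosomes."""
        haploid_pg = self.diploid_size_pg / 2.0
        return self.diploid_size_pg + self.b_count * self.b_fraction_of_haploid * haploid_pg

    @property
    def size_gb(self) -> float:
        return self.size_pg * self.pg_to_gb

    @property
    def size_bases(self) -> float:
        return self.size_gb * 1e9


def genome_size_gb(model: GenomeModel) -> float:
    """Effective genome size in Gb: (diploid + b_count·b_fraction·haploid) · pg_to_gb."""
    return model.size_gb


@dataclass(frozen=True)
class CopyNumberRecord:
    contig_id: str
    library_id: str
    mean_depth: float
    copies_per_haploid: float


def copies_per_haploid(mean_depth: float, library: LibraryInfo, model: GenomeModel) -> float:
    """Convert mean read depth to copies per haploid genome.

    Requires a gDNA library whose B count matches the genome model's, so the
    B-adjusted genome size is applied consistently.
    """
    if library.molecule != "gDNA":
        raise ValueError(
            f"copy number is defined for gDNA libraries, got {library.molecule} "
            f"({library.library_id})"
        )
    if library.b_count != model.b_count:
        raise ValueError(
            f"library {library.library_id} carries {library.b_count} B but the genome "
            f"model assumes {model.b_count}"
        )
    if mean_depth < 0:
        raise ValueError("mean_depth must be non-negative")
    return mean_depth * model.size_bases / (2.0 * library.total_bases)


def mean_region_depth(track: DepthTrack, start: int, end: int) -> float:
    """Arithmetic mean depth over [start, end) (0-based half-open)."""
    n = len(track.depth)
    if not (0 <= start < end <= n):
        raise ValueError(
            f"empty or out-of-bounds region [{start}, {end}) on {track.contig_id} (length {n})"
        )
    return float(np.mean(track.depth[start:end]))


def copy_number_table(
    tracks: Iterable[DepthTrack],
    libraries: Iterable[LibraryInfo],
    contigs: Iterable[ContigRecord],
    model: GenomeModel,
    region: str = "cds",
) -> pd.DataFrame:
    """Per-(contig, gDNA library) mean depth and copy number.

    ``region`` is ``"cds"`` (default; the quantified region is the CDS) or
    ``"full"`` for the whole contig.  RNA libraries are ignored.
    """
    if region not in ("cds", "full"):
        raise ValueError("region must be 'cds' or 'full'")
    lib_by_id = {l.library_id: l for l in libraries}
    contig_by_id = {c.contig_id: c for c in contigs}
    rows = []
    for track in tracks:
        lib = lib_by_id.get(track.library_id)
        if lib is None or lib.molecule != "gDNA":
            continue
        contig = contig_by_id[track.contig_id]
        if region == "cds":
            start, end = contig.cds_interval
        else:
            start, end = 0, contig.length
        d = mean_region_depth(track, start, end)
        c = copies_per_haploid(d, lib, model.with_b_count(lib.b_count))
        rows.append((track.contig_id, track.library_id, d, c))
    return pd.DataFrame(
        rows, columns=["contig_id", "library_id", "mean_depth", "copies_per_haploid"]
    )
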