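"""Transcription of B-chromosome paralogs, quantified at B-specific SNPs.

Because A- and B-derived reads map to the same reference contig, the only
reads attributable to the B paralog are those carrying its exclusive Alt
alleles.  For each gene we sum Ref- and Alt-allele RNA read counts over the
gene's passing SNP positions, normalize by transcript length to compare
across genes, and report the Alt/Ref ratio as the intensity of B-paralog
transcription relative to the A paralogs.  Genes without passing SNPs have
no measurable B expression and yield no record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ALLELE_INDEX, PileupCounts
from .snp_calling import SnpCall


@dataclass
class ExpressionRecord:
    gene: str
    library_id: str
    ref_reads: int
    alt_reads: int
    transcript_length: int
    n_snps: int

    def __post_init__(self):
        if self.transcript_length <= 0:
            raise ValueError("transcript_length must be positive")

    @property
    def ref_norm(self) -> float:
        return self.ref_reads / self.transcript_length

    @property
    def alt_norm(self) -> float:
        return self.alt_reads / self.transcript_length

    @property
    def alt_ref_ratio(self) -> float:
        """Alt/Ref ratio; inf when only Alt reads exist, NaN when neither."""
        if self.ref_reads > 0:
            return self.alt_reads / self.ref_reads
        return math.inf if self.alt_reads > 0 else math.nan


def count_alleles_at_snps(
    rna_pileup: PileupCounts,
    calls: Sequence[SnpCall],
    gene: str,
    transcript_length: int,
    library_id: str | None = None,
) -> ExpressionRecord | None:
    """Sum RNA Ref/Alt counts over a gene's PASS SNP positions.

    Returns None when the gene has no passing SNPs on this contig — the B
    paralog's expression is then unmeasurable by allele counting.
    """
    passing = [
        c for c in calls if c.verdict == "PASS" and c.contig_id == rna_pileup.contig_id
    ]
    if not passing:
        return None
    ref_total = 0
    alt_total = 0
    for call in passing:
        i = call.position - 1
        if not (0 <= i < rna_pileup.length):
            raise ValueError(
                f"SNP position {call.position} outside pileup of {rna_pileup.contig_id}"
            )
        ref_total += int(rna_pileup.counts[i, ALLELE_INDEX[call.ref_allele]])
        alt_total += int(rna_pileup.counts[i, ALLELE_INDEX[call.alt_allele]])
    return ExpressionRecord(
        gene=gene,
        library_id=library_id or rna_pileup.group_id,
        ref_reads=ref_total,
        alt_reads=alt_total,
        transcript_length=transcript_length,
        n_snps=len(passing),
    )


def b_transcript_profile(records: Sequence[ExpressionRecord]) -> dict[str, float]:
    """Share of total B-derived (length-normalized Alt) transcription per gene.

    Shares sum to 1 over genes with alt_norm > 0; an empty dict means no Alt
    reads were observed in the library at all.
    """
    if not records:
        raise ValueError("need at least one expression record")
    alt = {r.gene: r.alt_norm for r in records if r.alt_norm > 0}
    total = sum(alt.values())
    if total == 0:
        return {}
    return {g: v / total for g, v in alt.items()}


def expression_table(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene,
            "library_id": r.library_id,
            "ref_reads": r.ref_reads,
            "alt_reads": r.alt_reads,
            "transcript_length": r.transcript_length,
            "n_snps": r.n_snps,
            "ref_norm": r.ref_norm,
            "alt_norm": r.alt_norm,
            "alt_ref_ratio": r.alt_ref_ratio,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
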