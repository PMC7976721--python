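"""B-specific variant calling from merged pileup counts.

A B-specific variant is a position where the 0B genomic DNA is fixed for one
allele (Ref) while the 1B genomic DNA additionally carries an alternative
allele (Alt) absent from B-lacking genomes — the signature of a divergent
paralog on the B chromosome.  The filter cascade:

1. fixation — the 0B gDNA group shows at most ``max_0B_alt`` non-Ref reads;
2. proportion — in 1B gDNA the Ref count must not fall below the Alt count
   (a single extra B copy predicts Ref:Alt ≈ 2:1; direction configurable);
3. cross-species — the Alt allele must show fewer than two reads in every
   0B library of the sister species (gDNA or RNA), so shared ancestral
   polymorphism is excluded;
4. depth — both gDNA groups must reach a minimum total count.

Runs of adjacent passing indels of the same type are merged into single
mutational events.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ALLELES, ALLELE_INDEX, PileupCounts

GROUPS = ("gDNA_0B", "gDNA_1B", "RNA_0B", "RNA_1B")
BASES = ("A", "C", "G", "T")
VERDICTS = ("PASS", "not_fixed_0B", "ref_lt_alt_1B", "cross_species_alt", "low_depth")


@dataclass(frozen=True)
class SnpCallConfig:
    min_depth: int = 10           # per gDNA group, total counts at the site
    max_0B_alt: int = 0           # non-Ref reads tolerated in same-species 0B gDNA
    cross_species_max_alt: int = 1  # fail when any cross-species 0B library shows >= 2
    proportion_filter: str = "keep-ref-ge-alt"  # keep-ref-ge-alt | keep-alt-ge-ref | off

    def __post_init__(self):
        if self.proportion_filter not in ("keep-ref-ge-alt", "keep-alt-ge-ref", "off"):
            raise ValueError(f"unknown proportion_filter {self.proportion_filter!r}")


@dataclass
class SnpCall:
    """One candidate B-specific variant with per-group counts and a verdict."""

    contig_id: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    group_counts: dict  # group -> (ref_count, alt_count)
    cross_species_alt: int
    verdict: str
    event_id: int | None = None

    @property
    def is_indel(self) -> bool:
        return self.alt_allele in ("ins", "del")

    @property
    def variant_class(self) -> str:
        """s (substitution), i (insertion) or d (deletion)."""
        return {"ins": "i", "del": "d"}.get(self.alt_allele, "s")


def merge_group_pileups(pileups: Sequence[PileupCounts], group_id: str) -> dict[str, PileupCounts]:
    """Sum per-position counts of several libraries into one pileup per contig."""
    by_contig: dict[str, np.ndarray] = {}
    for p in pileups:
        if p.contig_id in by_contig:
            by_contig[p.contig_id] = by_contig[p.contig_id] + p.counts
        else:
            by_contig[p.contig_id] = p.counts.copy()
    return {
        c: PileupCounts(group_id=group_id, contig_id=c, counts=arr)
        for c, arr in by_contig.items()
    }


def _verdict(
    fix_fail: bool, prop_fail: bool, cross_fail: bool, depth_fail: bool
) -> str:
    """Fixed verdict priority; the PASS set does not depend on this order."""
    if fix_fail:
        return "not_fixed_0B"
    if prop_fail:
        return "ref_lt_alt_1B"
    if cross_fail:
        return "cross_species_alt"
    if depth_fail:
        return "low_depth"
    return "PASS"


def call_b_snps(
    pileups: Mapping[str, PileupCounts],
    cross_species: Sequence[PileupCounts] = (),
    cfg: SnpCallConfig = SnpCallConfig(),
) -> list[SnpCall]:
    """Call candidate B-specific variants on one contig.

    Parameters
    ----------
    pileups
        Merged per-group pileups keyed by group name; ``gDNA_0B`` and
        ``gDNA_1B`` are required, the RNA groups optional (their counts are
        recorded on the calls for downstream expression analysis).
    cross_species
        Per-library 0B pileups of the sister species (gDNA and RNA), used by
        the cross-species Alt filter.  Each entry is one library.
    """
    for required in ("gDNA_0B", "gDNA_1B"):
        if required not in pileups:
            raise ValueError(f"missing required pileup group {required!r}")
    p0 = pileups["gDNA_0B"]
    p1 = pileups["gDNA_1B"]
    if p0.length != p1.length or p0.contig_id != p1.contig_id:
        raise ValueError("group pileups must cover the same contig")
    contig = p0.contig_id
    xs = [x for x in cross_species if x.contig_id == contig]

    base_idx = [ALLELE_INDEX[b] for b in BASES]
    c0 = p0.counts
    c1 = p1.counts

    # candidate positions: 0B covered by a base allele, 1B shows any non-Ref reads
    ref_ix = np.argmax(c0[:, base_idx], axis=1)  # index into BASES
    has_ref = c0[:, base_idx].max(axis=1) > 0
    calls: list[SnpCall] = []
    candidate_pos = np.nonzero(has_ref)[0]
    for i in candidate_pos:
        r = int(ref_ix[i])
        ref = BASES[r]
        ref_col = ALLELE_INDEX[ref]
        non_ref_1b = [(a, int(c1[i, ALLELE_INDEX[a]])) for a in ALLELES if a != ref]
        alt, alt_count_1b = max(non_ref_1b, key=lambda t: (t[1], -ALLELE_INDEX[t[0]]))
        if alt_count_1b < 1:
            continue  # no alternative allele in 1B gDNA: not a candidate
        alt_col = ALLELE_INDEX[alt]

        ref_0b = int(c0[i, ref_col])
        alt_0b_total = int(c0[i].sum() - ref_0b)  # any non-Ref evidence in 0B
        ref_1b = int(c1[i, ref_col])

        fix_fail = alt_0b_total > cfg.max_0B_alt
        if cfg.proportion_filter == "keep-ref-ge-alt":
            prop_fail = ref_1b < alt_count_1b
        elif cfg.proportion_filter == "keep-alt-ge-ref":
            prop_fail = alt_count_1b < ref_1b
        else:
            prop_fail = False
        xs_alt = max((int(x.counts[i, alt_col]) for x in xs), default=0)
        cross_fail = xs_alt > cfg.cross_species_max_alt
        depth_fail = int(c0[i].sum()) < cfg.min_depth or int(c1[i].sum()) < cfg.min_depth

        group_counts = {
            "gDNA_0B": (ref_0b, int(c0[i, alt_col])),
            "gDNA_1B": (ref_1b, alt_count_1b),
        }
        for rna_group in ("RNA_0B", "RNA_1B"):
            if rna_group in pileups:
                cr = pileups[rna_group].counts
                group_counts[rna_group] = (int(cr[i, ref_col]), int(cr[i, alt_col]))
        calls.append(
            SnpCall(
                contig_id=contig,
                position=int(i) + 1,
                ref_allele=ref,
                alt_allele=alt,
                group_counts=group_counts,
                cross_species_alt=xs_alt,
                verdict=_verdict(fix_fail, prop_fail, cross_fail, depth_fail),
            )
        )
    calls.sort(key=lambda c: (c.contig_id, c.position, c.alt_allele))
    return calls


def merge_indel_events(calls: Sequence[SnpCall]) -> list[SnpCall]:
    """Assign event ids; adjacent PASS indels of one type share an event.

    Calls must cover whole contigs; they are sorted by (contig, position)
    internally.  Substitutions and non-PASS calls are singleton events.
    """
    ordered = sorted(calls, key=lambda c: (c.contig_id, c.position, c.alt_allele))
    next_id = 0
    prev: SnpCall | None = None
    for call in ordered:
        joins_prev = (
            prev is not None
            and call.verdict == "PASS"
            and prev.verdict == "PASS"
            and call.is_indel
            and prev.is_indel
            and call.alt_allele == prev.alt_allele
            and call.contig_id == prev.contig_id
            and call.position == prev.position + 1
        )
        if joins_prev:
            call.event_id = prev.event_id
        else:
            call.event_id = next_id
            next_id += 1
        prev = call
    return ordered


@dataclass
class VariantSummary:
    per_gene_snps: dict  # gene -> number of PASS SNPs
    class_counts: dict   # 's'/'d'/'i' -> PASS counts
    n_events: int
    n_pass: int


def summarize_variants(
    calls: Sequence[SnpCall], gene_of_contig: Mapping[str, str] | None = None
) -> VariantSummary:
    """Per-gene PASS counts plus substitution/deletion/insertion totals."""
    calls = merge_indel_events(calls) if any(c.event_id is None for c in calls) else list(calls)
    per_gene: dict[str, int] = defaultdict(int)
    class_counts = {"s": 0, "d": 0, "i": 0}
    events = set()
    n_pass = 0
    for c in calls:
        if c.verdict != "PASS":
            continue
        n_pass += 1
        gene = gene_of_contig.get(c.contig_id, c.contig_id) if gene_of_contig else c.contig_id
        per_gene[gene] += 1
        class_counts[c.variant_class] += 1
        events.add(c.event_id)
    return VariantSummary(
        per_gene_snps=dict(per_gene),
        class_counts=class_counts,
        n_events=len(events),
        n_pass=n_pass,
    )
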