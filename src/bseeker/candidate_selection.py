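"""Candidate selection: copy-number filters, genomic fold change, segmentation.

Contigs are first filtered on their 0B copy number (too low suggests mapping
or assembly artefacts, too high repetitive DNA).  The genomic fold change
(gFC) of a contig in a B-carrying individual is the log2 ratio of its copy
number there to the mean over the B-lacking individuals; one extra B-linked
copy of a single-copy gene predicts log2(3/2).  With replicated 1B
individuals a contig is a candidate when every replicate reaches the
threshold; with a single 1B individual a conservative higher threshold is
used instead.

Coverage-pattern classification splits the per-position (pooled 1B)/(pooled
0B) depth ratio at abrupt changes: a single segment is the uniform-coverage
(UC) pattern, several segments irregular coverage (IC) with segments
labelled high-coverage (HC) or low-coverage (LC) relative to the contig-wide
mean log2 ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import DepthTrack

#: Exact one-extra-copy threshold log2(3/2); printed as 0.585.
GFC_ONE_EXTRA_COPY = math.log2(1.5)


@dataclass(frozen=True)
class SelectionConfig:
    min_copies_0B: float = 0.5
    max_copies_0B: float = 4.0
    gfc_threshold_multi: float = GFC_ONE_EXTRA_COPY
    gfc_threshold_single: float = 1.0
    require_all_replicates: bool = True
    min_seg_len: int = 100
    ratio_jump: float = 1.3

    def __post_init__(self):
        if not self.min_copies_0B < self.max_copies_0B:
            raise ValueError("min_copies_0B must be < max_copies_0B")
        if self.gfc_threshold_multi <= 0 or self.gfc_threshold_single <= 0:
            raise ValueError("gFC thresholds must be positive")
        if self.min_seg_len < 1:
            raise ValueError("min_seg_len must be >= 1")
        if self.ratio_jump <= 1:
            raise ValueError("ratio_jump must be > 1")


@dataclass
class GfcRecord:
    contig_id: str
    gfc: np.ndarray  # one value per 1B individual
    mean_copies_0B: float
    selected: bool = False
    pattern: str = "undetermined"  # UC | IC | undetermined

    def __post_init__(self):
        self.gfc = np.asarray(self.gfc, dtype=float)


@dataclass(frozen=True)
class Segment:
    contig_id: str
    start: int  # 0-based half-open
    end: int
    label: str  # HC | LC
    mean_ratio: float  # mean log2(1B/0B) over the segment


def copy_filter(copy_table: pd.DataFrame, libraries, cfg: SelectionConfig) -> set[str]:
    """Contigs whose mean 0B copy number lies in [min, max] (inclusive).

    ``copy_table`` is the output of :func:`bseeker.copy_number.copy_number_table`;
    only gDNA libraries with b_count == 0 contribute.
    """
    lib_by_id = {l.library_id: l for l in libraries}
    is_0b = copy_table["library_id"].map(
        lambda i: lib_by_id[i].molecule == "gDNA" and lib_by_id[i].b_count == 0
    )
    zero_b = copy_table[is_0b]
    if zero_b.empty:
        raise ValueError("no 0B gDNA libraries in the copy-number table")
    means = zero_b.groupby("contig_id")["copies_per_haploid"].mean()
    kept = means[(means >= cfg.min_copies_0B) & (means <= cfg.max_copies_0B)]
    return set(kept.index)


def mean_copies_0B(copy_table: pd.DataFrame, libraries) -> pd.Series:
    """Per-contig mean 0B copy number (helper shared by filter and gFC)."""
    lib_by_id = {l.library_id: l for l in libraries}
    is_0b = copy_table["library_id"].map(
        lambda i: lib_by_id[i].molecule == "gDNA" and lib_by_id[i].b_count == 0
    )
    return copy_table[is_0b].groupby("contig_id")["copies_per_haploid"].mean()


def compute_gfc(contig_id: str, copies_1B: Sequence[float], copies_0B: Sequence[float]) -> GfcRecord:
    """Per-1B-individual gFC = log2(copies_1B_i / mean(copies_0B)).

    A non-positive 0B mean leaves the record flagged unselectable
    (gFC all NaN) rather than raising: such contigs are simply never
    candidates.
    """
    copies_1B = np.asarray(copies_1B, dtype=float)
    copies_0B = np.asarray(copies_0B, dtype=float)
    if copies_1B.size == 0 or copies_0B.size == 0:
        raise ValueError("need at least one copy-number value per group")
    m0 = float(np.mean(copies_0B))
    if m0 <= 0:
        return GfcRecord(contig_id, np.full(copies_1B.shape, np.nan), m0, selected=False)
    with np.errstate(divide="ignore"):
        gfc = np.log2(copies_1B / m0)
    return GfcRecord(contig_id, gfc, m0)


def select_candidates(
    records: Iterable[GfcRecord], cfg: SelectionConfig, n_1B: int
) -> set[str]:
    """Apply the gFC threshold rule and mark records selected.

    Multi-replicate mode (n_1B > 1, require_all_replicates): every 1B
    individual's gFC must reach ``gfc_threshold_multi``.  Single-replicate
    mode (n_1B == 1): the single gFC must reach ``gfc_threshold_single``.
    """
    if n_1B < 1:
        raise ValueError("need at least one 1B individual")
    selected = set()
    for rec in records:
        g = rec.gfc
        if np.isnan(g).any():
            rec.selected = False
            continue
        if n_1B == 1:
            ok = bool(g[0] >= cfg.gfc_threshold_single)
        elif cfg.require_all_replicates:
            ok = bool(np.all(g >= cfg.gfc_threshold_multi))
        else:
            ok = bool(np.mean(g) >= cfg.gfc_threshold_multi)
        rec.selected = ok
        if ok:
            selected.add(rec.contig_id)
    return selected


def gfc_table(records: Iterable[GfcRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {"contig_id": rec.contig_id, "mean_copies_0B": rec.mean_copies_0B,
               "selected": rec.selected, "pattern": rec.pattern}
        for i, g in enumerate(rec.gfc, start=1):
            row[f"gfc_1B_{i}"] = g
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coverage-pattern segmentation
# ---------------------------------------------------------------------------

def pooled_ratio(
    tracks_1B: Sequence[DepthTrack],
    tracks_0B: Sequence[DepthTrack],
    libraries,
) -> np.ndarray:
    """Per-position (pooled 1B)/(pooled 0B) depth ratio, library-size normalized.

    Depths are summed within each genotype group and divided by the group's
    total sequenced bases before taking the ratio; positions with zero
    pooled 0B depth are NaN (masked).
    """
    lib_by_id = {l.library_id: l for l in libraries}
    d1 = np.sum([t.depth for t in tracks_1B], axis=0).astype(float)
    d0 = np.sum([t.depth for t in tracks_0B], axis=0).astype(float)
    l1 = sum(lib_by_id[t.library_id].total_bases for t in tracks_1B)
    l0 = sum(lib_by_id[t.library_id].total_bases for t in tracks_0B)
    ratio = np.full(d1.shape, np.nan)
    ok = d0 > 0
    ratio[ok] = (d1[ok] / l1) / (d0[ok] / l0)
    return ratio


def _segment_sse(prefix: np.ndarray, prefix_sq: np.ndarray, counts: np.ndarray,
                 i: int, j: int) -> tuple[float, float, int]:
    """(sse, mean, n_valid) of log2 ratio over [i, j) using prefix sums."""
    n = counts[j] - counts[i]
    if n == 0:
        return 0.0, 0.0, 0
    s = prefix[j] - prefix[i]
    sq = prefix_sq[j] - prefix_sq[i]
    mean = s / n
    return max(sq - n * mean * mean, 0.0), mean, int(n)


def segment_coverage(
    ratio: np.ndarray, min_seg_len: int = 100, ratio_jump: float = 1.3
) -> tuple[list[tuple[int, int, float]], str]:
    """Change-point segmentation of a per-position depth-ratio array.

    Recursive binary splitting on the log2 ratio: each candidate split
    minimizes within-segment squared error and is accepted only if both
    sides span at least ``min_seg_len`` positions and their mean log2 ratios
    differ by at least ``log2(ratio_jump)``.  Returns ``(segments, pattern)``
    where each segment is ``(start, end, mean_log2_ratio)`` on 0-based
    half-open coordinates, and pattern is ``"UC"`` for a single segment,
    ``"IC"`` for several, ``"undetermined"`` if every position is masked.
    """
    ratio = np.asarray(ratio, dtype=float)
    n = ratio.size
    valid = np.isfinite(ratio) & (ratio > 0)
    if not valid.any():
        return [], "undetermined"
    log_r = np.zeros(n)
    log_r[valid] = np.log2(ratio[valid])
    w = valid.astype(float)
    prefix = np.concatenate([[0.0], np.cumsum(log_r * w)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(log_r * log_r * w)])
    counts = np.concatenate([[0], np.cumsum(valid.astype(int))])
    min_jump = math.log2(ratio_jump)

    segments: list[tuple[int, int, float]] = []

    def split(i: int, j: int) -> None:
        best = None
        # candidate cut points keep both sides >= min_seg_len raw positions
        for k in range(i + min_seg_len, j - min_seg_len + 1):
            sse_l, mean_l, n_l = _segment_sse(prefix, prefix_sq, counts, i, k)
            sse_r, mean_r, n_r = _segment_sse(prefix, prefix_sq, counts, k, j)
            if n_l == 0 or n_r == 0:
                continue
            if abs(mean_l - mean_r) < min_jump:
                continue
            total = sse_l + sse_r
            if best is None or total < best[0]:
                best = (total, k)
        if best is None:
            _, mean, _ = _segment_sse(prefix, prefix_sq, counts, i, j)
            segments.append((i, j, mean))
            return
        split(i, best[1])
        split(best[1], j)

    split(0, n)
    pattern = "UC" if len(segments) == 1 else "IC"
    return segments, pattern


def label_segments(
    contig_id: str, segments: Sequence[tuple[int, int, float]]
) -> list[Segment]:
    """Label segments HC/LC relative to the contig-wide mean log2 ratio.

    Adjacent segments that end up with the same label are merged (their mean
    recomputed as a length-weighted average) so consecutive segments always
    alternate labels.
    """
    if not segments:
        return []
    lengths = np.array([e - s for s, e, _ in segments], dtype=float)
    means = np.array([m for _, _, m in segments])
    overall = float(np.sum(means * lengths) / np.sum(lengths))
    labelled = [
        (s, e, "HC" if m > overall else "LC", m) for (s, e, m) in segments
    ]
    merged: list[list] = []
    for s, e, lab, m in labelled:
        if merged and merged[-1][2] == lab:
            prev = merged[-1]
            w_prev, w_new = prev[1] - prev[0], e - s
            prev[3] = (prev[3] * w_prev + m * w_new) / (w_prev + w_new)
            prev[1] = e
        else:
            merged.append([s, e, lab, m])
    return [Segment(contig_id, s, e, lab, m) for s, e, lab, m in merged]


def classify_pattern(
    contig_id: str, ratio: np.ndarray, cfg: SelectionConfig
) -> tuple[list[Segment], str]:
    """Segment a contig's 1B/0B ratio track and label HC/LC regions."""
    raw, pattern = segment_coverage(ratio, cfg.min_seg_len, cfg.ratio_jump)
    segs = label_segments(contig_id, raw)
    # merging same-label neighbours can collapse IC back to a single segment
    if len(segs) == 1:
        pattern = "UC" if pattern != "undetermined" else pattern
    return segs, pattern
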