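"""qPCR relative-quantification arithmetic and estimation statistics.

Relative quantity against a single-copy reference gene: RQ = 2^-(dCt) with
dCt = Ct_target - Ct_reference.  Expression is reported as the normalized
relative expression quantity NREQ = 2^-(ddCt), calibrated to the mean dCt
of the 0B group (so the calibrator group's geometric-mean NREQ is exactly 1).
Two-group comparisons use an estimation approach: the mean difference with a
percentile bootstrap confidence interval, reported instead of a p-value.
Technical replicates are averaged per biological sample before any group
statistic.  When only a single B-carrying individual could be assayed, a
gene is accepted as B-linked only if that individual's RQ exceeds every
B-lacking individual's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: target and reference Ct for a sample/replicate."""

    sample_id: str
    group: str  # '0B' or '1B'
    target_gene: str
    ct_target: float
    ct_reference: float
    replicate_id: int = 1

    def __post_init__(self):
        if not (np.isfinite(self.ct_target) and np.isfinite(self.ct_reference)):
            raise ValueError("Ct values must be finite")
        if self.group not in ("0B", "1B"):
            raise ValueError("group must be '0B' or '1B'")


@dataclass(frozen=True)
class EffectSize:
    mean_diff: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    validated: bool

    def __post_init__(self):
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must be <= ci_high")


def rq_dct(ct: CtRecord) -> float:
    """Relative quantity, RQ = 2^-(Ct_target - Ct_reference)."""
    return 2.0 ** -(ct.ct_target - ct.ct_reference)


def collapse_replicates(records: Sequence[CtRecord]) -> pd.DataFrame:
    """Average technical replicates per (sample, gene); returns per-sample dCt."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "group": [r.group for r in records],
            "target_gene": [r.target_gene for r in records],
            "dct": [r.ct_target - r.ct_reference for r in records],
        }
    )
    return (
        df.groupby(["sample_id", "group", "target_gene"], as_index=False)["dct"].mean()
    )


def nreq_ddct(records: Sequence[CtRecord], calibrator_group: str = "0B") -> pd.DataFrame:
    """Per-sample NREQ = 2^-(dCt_s - mean dCt of the calibrator group).

    Technical replicates are averaged per sample first.  Raises if the
    calibrator group is empty.
    """
    per_sample = collapse_replicates(records)
    out = []
    for gene, sub in per_sample.groupby("target_gene"):
        cal = sub.loc[sub["group"] == calibrator_group, "dct"]
        if cal.empty:
            raise ValueError(f"calibrator group {calibrator_group!r} empty for {gene}")
        ddct = sub["dct"] - cal.mean()
        sub = sub.assign(nreq=2.0 ** -ddct)
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def gardner_altman(
    group0: Sequence[float],
    group1: Sequence[float],
    n_boot: int = 5000,
    seed: int = 0,
) -> EffectSize:
    """Mean difference (group1 - group0) with a 95% percentile bootstrap CI.

    Each group is resampled with replacement independently; ``validated`` is
    True when the interval excludes zero from below (ci_low > 0).
    """
    g0 = np.asarray(group0, dtype=float)
    g1 = np.asarray(group1, dtype=float)
    if g0.size == 0 or g1.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx0 = rng.integers(0, g0.size, size=(n_boot, g0.size))
    idx1 = rng.integers(0, g1.size, size=(n_boot, g1.size))
    diffs = g1[idx1].mean(axis=1) - g0[idx0].mean(axis=1)
    ci_low, ci_high = np.percentile(diffs, [2.5, 97.5])
    return EffectSize(
        mean_diff=float(g1.mean() - g0.mean()),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        seed=seed,
        validated=bool(ci_low > 0),
    )


def single_individual_rule(rq_1B: float, rq_0B: Sequence[float]) -> bool:
    """With one 1B individual: B-linked iff its RQ strictly exceeds every 0B RQ."""
    rq_0B = np.asarray(rq_0B, dtype=float)
    if rq_0B.size == 0:
        raise ValueError("need at least one 0B value")
    return bool(rq_1B > rq_0B.max())


def validate_genes(
    records: Sequence[CtRecord], n_boot: int = 5000, seed: int = 0
) -> pd.DataFrame:
    """Per-gene B-linkage validation from gDNA qPCR RQ values.

    With >= 2 samples per group the Gardner-Altman rule applies (bootstrap CI
    of the 1B-0B mean RQ difference excludes zero); with a single 1B sample
    the strict single-individual rule applies.
    """
    per_sample = collapse_replicates(records)
    per_sample = per_sample.assign(rq=2.0 ** -per_sample["dct"])
    rows = []
    for gene, sub in per_sample.groupby("target_gene"):
        rq0 = sub.loc[sub["group"] == "0B", "rq"].to_numpy()
        rq1 = sub.loc[sub["group"] == "1B", "rq"].to_numpy()
        if rq1.size == 0 or rq0.size == 0:
            continue
        if rq1.size == 1:
            validated = single_individual_rule(float(rq1[0]), rq0)
            mean_diff = float(rq1.mean() - rq0.mean())
            ci_low = ci_high = np.nan
        else:
            es = gardner_altman(rq0, rq1, n_boot=n_boot, seed=seed)
            validated, mean_diff = es.validated, es.mean_diff
            ci_low, ci_high = es.ci_low, es.ci_high
        rows.append(
            {
                "target_gene": gene,
                "n_0B": rq0.size,
                "n_1B": rq1.size,
                "mean_rq_0B": float(rq0.mean()),
                "mean_rq_1B": float(rq1.mean()),
                "mean_diff": mean_diff,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "validated": bool(validated),
            }
        )
    return pd.DataFrame(rows)
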