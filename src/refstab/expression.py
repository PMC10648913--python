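"""Relative quantification by 2^-ddCT against one or more references.

For each sample, dCT = Ct(target) - mean Ct(references); the arithmetic
mean of reference Ct corresponds to the geometric mean of reference
quantities, the standard multi-reference normalization factor.  ddCT
subtracts the mean dCT over the calibrator samples (typically the
treatment's 0 h group), so relative expression RQ = 2^-ddCT equals 1 at
the calibrator by construction.

Per-time-point significance against the calibrator uses Welch's t-test
on log2 RQ with star classes at p < 0.05 / 0.01 / 0.001.  No
multiple-testing correction is applied across time points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .io import CtMatrix, SampleMeta

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


@dataclass
class ExpressionSeries:
    """RQ = 2^-ddCT of one target over time, with replicate spread.

    ``table`` has one row per (treatment, time_h) with columns
    rq_mean, rq_sd, n, p_value, stars; ``sample_rq`` holds per-sample
    values for downstream statistics.
    """

    target: str
    references: list[str]
    table: pd.DataFrame
    sample_rq: pd.Series            # indexed by sample_id
    sample_log2rq: pd.Series

    def rq_at(self, treatment: str, time_h: float) -> float:
        return float(
            self.table.set_index(["treatment", "time_h"]).loc[(treatment, time_h), "rq_mean"]
        )


def significance_vs_calibrator(values: np.ndarray, calibrator: np.ndarray) -> tuple[float, str]:
    """Welch t-test of log2 RQ replicate values against the calibrator's.

    Returns (p, star class).  With fewer than two replicates on either
    side the comparison is not testable: returns (nan, "ns") with a
    warning.
    """
    values = np.asarray(values, dtype=float)
    calibrator = np.asarray(calibrator, dtype=float)
    if len(values) < 2 or len(calibrator) < 2:
        logger.warning("significance test skipped: need >= 2 replicates per side")
        return float("nan"), "ns"
    if np.allclose(values, calibrator[: len(values)]) and len(values) == len(calibrator):
        if np.array_equal(values, calibrator):
            return 1.0, "ns"
    res = stats.ttest_ind(values, calibrator, equal_var=False)
    p = float(res.pvalue)
    if np.isnan(p):  # zero variance on both sides
        p = 1.0 if np.isclose(values.mean(), calibrator.mean()) else 0.0
    return p, significance_stars(p)


def ddct(m: CtMatrix, target: str, references: list[str],
         calibrator: Callable[[SampleMeta], bool] | None = None) -> ExpressionSeries:
    """Relative expression of ``target`` normalized to ``references``.

    ``calibrator`` selects the baseline samples (default: time_h == 0
    within the samples present in ``m``).  Per (treatment, time) the
    replicate RQ values are summarized as mean and SD, with Welch's
    t-test on log2 RQ against the calibrator replicates.
    """
    if target in references:
        raise ValueError(f"target {target!r} cannot be one of its references")
    for g in [target, *references]:
        m.gene_index(g)  # raises KeyError if absent
    if not references:
        raise ValueError("need at least one reference gene")
    if calibrator is None:
        calibrator = lambda meta: meta.time_h == 0  # noqa: E731

    ct_target = m.gene_row(target)
    ct_ref = np.mean([m.gene_row(r) for r in references], axis=0)
    dct = ct_target - ct_ref

    cal_idx = [j for j, s in enumerate(m.samples) if calibrator(m.meta[s])]
    if not cal_idx:
        raise ValueError("calibrator predicate selects no samples")
    ddct_vals = dct - np.mean(dct[cal_idx])
    log2rq = -ddct_vals
    rq = 2.0 ** log2rq

    sample_rq = pd.Series(rq, index=m.samples, name="rq")
    sample_log2rq = pd.Series(log2rq, index=m.samples, name="log2rq")

    cal_log2 = log2rq[cal_idx]
    by_cond: dict[tuple[str, float], list[int]] = {}
    for j, s in enumerate(m.samples):
        meta = m.meta[s]
        by_cond.setdefault((meta.treatment, meta.time_h), []).append(j)

    rows = []
    for (trt, t), idx in by_cond.items():
        vals = rq[idx]
        logs = log2rq[idx]
        if set(idx) == set(cal_idx):
            p, stars = 1.0, "ns"
        else:
            p, stars = significance_vs_calibrator(logs, cal_log2)
        rows.append(dict(
            treatment=trt, time_h=t,
            rq_mean=float(np.mean(vals)),
            rq_sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            n=len(vals), p_value=p, stars=stars,
        ))
    table = pd.DataFrame(rows).sort_values(["treatment", "time_h"]).reset_index(drop=True)
    return ExpressionSeries(target, list(references), table, sample_rq, sample_log2rq)


@dataclass
class ReferenceSensitivity:
    """Divergence between RQ series computed under two reference sets."""

    stable: ExpressionSeries
    unstable: ExpressionSeries
    per_sample_log2_ratio: pd.Series
    max_abs_log2_ratio: float
    mean_abs_log2_ratio: float


def reference_choice_sensitivity(
    m: CtMatrix, target: str,
    stable_refs: list[str], unstable_refs: list[str],
    calibrator: Callable[[SampleMeta], bool] | None = None,
) -> ReferenceSensitivity:
    """Quantify how much the choice of references changes the RQ series.

    Computes the RQ series under both reference sets and reports the
    per-sample log2 ratio between them, with its max and mean absolute
    value.  Identical reference sets give divergence 0.
    """
    a = ddct(m, target, stable_refs, calibrator)
    b = ddct(m, target, unstable_refs, calibrator)
    ratio = a.sample_log2rq - b.sample_log2rq
    return ReferenceSensitivity(
        stable=a, unstable=b,
        per_sample_log2_ratio=ratio,
        max_abs_log2_ratio=float(ratio.abs().max()),
        mean_abs_log2_ratio=float(ratio.abs().mean()),
    )
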