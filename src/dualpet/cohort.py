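"""Cohort-level statistics and the embedded reference animal table.

The reference table carries the per-animal target-to-background ratios of
the original dual-tracer study: 10 tumor-bearing mice and the 4 of 14
controls whose choline scan showed a hot spot, each with an FCH TBR and a
fused-image FDG TBR (mean ± voxel SD), plus bioluminescence ratios for the
tumor group carried as opaque annotation. Group summaries use the sample
SD (n-1). Both the classical pooled-variance Student's t test and the
Welch unequal-variance variant are provided; pooled is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detect import BackgroundEstimate
from .quantify import DEFAULT_TAU, MouseRecord, TbrResult

__all__ = [
    "CohortTable",
    "GroupSummary",
    "TTestResult",
    "load_table1_fixture",
    "group_summary",
    "two_sample_t",
    "diagnostic_rates",
    "TABLE1_CONTROL_COHORT_N",
]

# Reference study design: 14 controls scanned, 4 with an FCH hot spot.
TABLE1_CONTROL_COHORT_N = 14

# (fch_tbr, fch_sd, fused_tbr, fused_sd) per FCH-positive control animal
_TABLE1_CONTROL = [
    (2.05, 0.10, 1.03, 0.06),
    (1.25, 0.06, 0.99, 0.00),
    (1.26, 0.10, 0.98, 0.01),
    (2.45, 0.60, 1.14, 0.07),
]

# (fch_tbr, fch_sd, fused_tbr, fused_sd, bli_ratio) per tumor-bearing animal
_TABLE1_TUMOR = [
    (2.24, 0.11, 1.63, 0.04, 15.17),
    (4.06, 0.32, 1.47, 0.07, 12.53),
    (2.37, 0.39, 1.36, 0.05, 11.01),
    (2.62, 0.33, 1.14, 0.06, 16.52),
    (4.24, 0.85, 1.29, 0.04, 24.52),
    (2.51, 0.43, 1.28, 0.01, 12.20),
    (3.31, 0.38, 1.12, 0.02, 6.26),
    (2.21, 0.76, 1.27, 0.17, 22.63),
    (1.08, 0.34, 2.35, 0.06, 89.66),
    (1.82, 0.09, 1.79, 0.16, 61.91),
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample summary of one group's values: n, mean, SD (n-1), min, max."""

    n: int
    mean: float
    sd: float
    min: float
    max: float
    degenerate: bool = False  # True for n=1 where the SD is undefined

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class TTestResult:
    """Unpaired two-sided t comparison of two groups."""

    t_statistic: float
    degrees_of_freedom: float
    p_two_sided: float
    variant: str  # "pooled" | "welch"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_two_sided <= 1.0:
            raise ValueError("p must lie in (0, 1]")
        if self.degrees_of_freedom <= 0:
            raise ValueError("df must be > 0")


@dataclass
class CohortTable:
    """Per-animal records of one two-group study.

    ``control_cohort_n`` is the number of control animals scanned, which
    can exceed the number of control *records* when hot-spot-free controls
    are not tabulated (as in the reference table: 4 rows, 14 scanned).
    """

    records: list[MouseRecord]
    control_cohort_n: int
    provenance: str  # "fixture_table1" | "simulated"

    def __post_init__(self) -> None:
        ids = [r.mouse_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("mouse_ids must be unique")

    def group_records(self, group: str) -> list[MouseRecord]:
        return [r for r in self.records if r.group == group]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "mouse_id": r.mouse_id,
                    "group": r.group,
                    "fch_tbr": r.fch_tbr.ratio if r.fch_tbr else np.nan,
                    "fch_tbr_sd": r.fch_tbr.ratio_sd if r.fch_tbr else np.nan,
                    "fused_tbr": r.fused_tbr.ratio if r.fused_tbr else np.nan,
                    "fused_tbr_sd": r.fused_tbr.ratio_sd if r.fused_tbr else np.nan,
                    "call": r.call,
                    "bli_ratio": r.bli_ratio if r.bli_ratio is not None else np.nan,
                }
            )
        return pd.DataFrame(rows)


def _fixture_tbr(context: str, ratio: float, sd: float, roi_id: int) -> TbrResult:
    bg = BackgroundEstimate(mean_counts_per_voxel=1.0, sd_counts_per_voxel=0.0, n_voxels=1)
    return TbrResult(
        tracer_context=context,
        ratio=ratio,
        ratio_sd=sd,
        roi_id=roi_id,
        n_roi_voxels=1,
        background_used=bg,
    )


def load_table1_fixture(tau: float = DEFAULT_TAU) -> CohortTable:
    """The reference study's per-animal TBR table as a :class:`CohortTable`.

    Calls are re-derived from the tabulated fused ratios with the decision
    threshold ``tau`` rather than hard-coded, so the classifier's verdict
    on every tabulated animal is always the live rule's verdict.
    """
    records: list[MouseRecord] = []
    for i, (fch, fch_sd, fused, fused_sd) in enumerate(_TABLE1_CONTROL, start=1):
        call = "tumor" if fused > tau else "fch_false_positive"
        records.append(
            MouseRecord(
                mouse_id=f"control_{i}",
                group="control",
                fch_tbr=_fixture_tbr("FCH", fch, fch_sd, i),
                fused_tbr=_fixture_tbr("FUSED_FDG", fused, fused_sd, i),
                call=call,
            )
        )
    for i, (fch, fch_sd, fused, fused_sd, bli) in enumerate(_TABLE1_TUMOR, start=1):
        call = "tumor" if fused > tau else "fch_false_positive"
        records.append(
            MouseRecord(
                mouse_id=f"tumor_{i}",
                group="tumor_bearing",
                fch_tbr=_fixture_tbr("FCH", fch, fch_sd, i),
                fused_tbr=_fixture_tbr("FUSED_FDG", fused, fused_sd, i),
                call=call,
                bli_ratio=bli,
            )
        )
    return CohortTable(
        records=records,
        control_cohort_n=TABLE1_CONTROL_COHORT_N,
        provenance="fixture_table1",
    )


def group_summary(values: Sequence[float]) -> GroupSummary:
    """Sample mean, SD (n-1 denominator), min and max of a group."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    if arr.size == 1:
        v = float(arr[0])
        return GroupSummary(n=1, mean=v, sd=0.0, min=v, max=v, degenerate=True)
    return GroupSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        min=float(arr.min()),
        max=float(arr.max()),
    )


def two_sample_t(
    a: Sequence[float], b: Sequence[float], variant: str = "pooled"
) -> TTestResult:
    """Unpaired two-sided t test between groups ``a`` and ``b``.

    ``pooled`` is the classical equal-variance Student's t with
    df = n_a + n_b - 2; ``welch`` uses the unequal-variance statistic with
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_two_sided=float(res.pvalue),
        variant=variant,
    )


def diagnostic_rates(
    cohort: CohortTable, tau: float = DEFAULT_TAU
) -> tuple[float, float, int]:
    """Sensitivity, FCH-only false-positive rate, residual control positives.

    Sensitivity (%): tumor-bearing animals with an FCH hot spot whose fused
    TBR exceeds ``tau``, over all tumor-bearing animals. FCH false-positive
    rate (%): controls with any FCH hot spot over all scanned controls
    (``control_cohort_n``) — the single-tracer error rate the fused rule is
    meant to repair. Residual count: controls still called tumor after the
    fused-image rule.
    """
    tumors = cohort.group_records("tumor_bearing")
    controls = cohort.group_records("control")
    if not tumors or cohort.control_cohort_n <= 0:
        raise ValueError("cohort must contain tumor-bearing animals and controls")
    n_called = sum(
        1
        for r in tumors
        if r.fch_tbr is not None and r.fused_tbr is not None and r.fused_tbr.ratio > tau
    )
    sensitivity = 100.0 * n_called / len(tumors)
    n_fch_positive_controls = sum(1 for r in controls if r.fch_tbr is not None)
    fp_rate = 100.0 * n_fch_positive_controls / cohort.control_cohort_n
    residual = sum(
        1 for r in controls if r.fused_tbr is not None and r.fused_tbr.ratio > tau
    )
    return sensitivity, fp_rate, residual
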