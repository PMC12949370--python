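"""DNA double-strand-break foci statistics.

Repair-protein foci (e.g. 53BP1) counted per nucleus are a per-cell readout
of residual DNA double-strand breaks. Sensitizer effect is summarized as
the relative increase in mean foci/cell of the treated arm over control,
tested with a pooled-variance (equal-variance) two-sample t-test on the
per-cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FociRecord",
    "FociComparison",
    "TTestResult",
    "mean_foci_per_cell",
    "relative_increase",
    "equal_variance_t_test",
    "compare_foci",
]


@dataclass(frozen=True)
class FociRecord:
    """Foci count for one nucleus under one condition."""

    modality: str
    dose_rate: float
    arm: str
    cell_id: int
    n_foci: int

    def __post_init__(self) -> None:
        if self.n_foci < 0:
            raise ValueError("n_foci must be >= 0")


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


@dataclass
class FociComparison:
    """Treated-vs-control foci summary for one condition."""

    mean_ctrl: float
    mean_treat: float
    relative_increase_pct: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float


def _counts(records_or_counts) -> np.ndarray:
    vals = [r.n_foci if isinstance(r, FociRecord) else r for r in records_or_counts]
    return np.asarray(vals, dtype=float)


def mean_foci_per_cell(records: Iterable) -> float:
    """Arithmetic mean foci/cell over one condition's cells."""
    counts = _counts(records)
    if counts.size == 0:
        raise ValueError("no foci records for condition")
    return float(counts.mean())


def relative_increase(mean_treat: float, mean_ctrl: float) -> float:
    """Percent increase of the treated mean over the control mean."""
    if mean_ctrl <= 0:
        raise ValueError("control mean must be > 0")
    return 100.0 * (mean_treat - mean_ctrl) / mean_ctrl


def equal_variance_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> TTestResult:
    """Two-tailed pooled-variance two-sample t-test.

    df = n_a + n_b - 2. Two constant, equal samples give (t=0, p=1); two
    constant samples with different values are reported as infinitely
    separated (p=0).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    df = int(a.size + b.size - 2)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0)
        return TTestResult(float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0)
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def compare_foci(
    records: Iterable[FociRecord],
    ctrl_label: str = "CTRL",
    treat_label: str = "GNP",
) -> FociComparison:
    """Compare treated vs control per-cell foci counts for one condition."""
    records = list(records)
    ctrl = _counts([r for r in records if r.arm == ctrl_label])
    treat = _counts([r for r in records if r.arm == treat_label])
    if ctrl.size == 0 or treat.size == 0:
        raise ValueError("both arms must have foci records")
    m_c, m_t = float(ctrl.mean()), float(treat.mean())
    t, df, p = equal_variance_t_test(treat, ctrl)
    return FociComparison(
        mean_ctrl=m_c,
        mean_treat=m_t,
        relative_increase_pct=relative_increase(m_t, m_c),
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
    )
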