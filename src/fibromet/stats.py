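"""Group summaries, one-way ANOVA comparisons, power simulation and
transglutaminase-activity normalization.

Group measurements are reported as mean ± SD (sample SD, n−1 denominator)
with median and range; groups are compared by classical one-way ANOVA with
significance at p < 0.05 and no multiple-testing correction (each parameter
is tested on its own; the output flags this). For two groups the F statistic
equals the square of the pooled-variance t statistic, which the test suite
uses as an independent cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ParameterError
from .synthgen import sample_group_measurements

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "PowerResult",
    "summarize",
    "anova_oneway",
    "power_simulation",
    "tg_normalize",
    "fold_change",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD (plus median and range) of one parameter in one group."""

    parameter: str
    group: str
    n: int
    mean: float
    sd: float
    median: float
    minimum: float
    maximum: float


@dataclass(frozen=True)
class ComparisonResult:
    """One-way ANOVA comparison of a parameter across groups."""

    parameter: str
    f_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class PowerResult:
    """Outcome of a two-group simulation study."""

    rejection_rate: float
    median_p: float
    reps: int


def summarize(values: Sequence[float], label: str = "", parameter: str = "") -> GroupSummary:
    """Mean, sample SD (n−1), n, median and range of one group."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 2:
        raise ParameterError("summarize requires at least two values")
    return GroupSummary(
        parameter=parameter,
        group=label,
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        median=float(np.median(arr)),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
    )


def anova_oneway(*groups: Sequence[float], parameter: str = "") -> ComparisonResult:
    """Classical one-way ANOVA over two or more groups.

    F is the between/within mean-square ratio with (k−1, N−k) degrees of
    freedom and p comes from the F distribution. Degenerate inputs are
    defined rather than erroneous: all values identical across all groups
    gives F = 0, p = 1; distinct group means with zero within-group variance
    give F = ∞, p = 0.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and \
            len(groups[0]) and hasattr(groups[0][0], "__len__"):
        groups = tuple(groups[0])  # accept a single list-of-groups too
    if len(groups) < 2:
        raise ParameterError("ANOVA requires at least two groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ParameterError("every group needs at least two values")

    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            return ComparisonResult(parameter=parameter, f_statistic=0.0, p_value=1.0)
        return ComparisonResult(parameter=parameter, f_statistic=np.inf, p_value=0.0)
    f, p = sps.f_oneway(*arrays)
    return ComparisonResult(parameter=parameter, f_statistic=float(f), p_value=float(p))


def power_simulation(
    mean_a: float,
    sd_a: float,
    mean_b: float,
    sd_b: float,
    n: int,
    reps: int = 2000,
    alpha: float = ALPHA,
    seed: int = 0,
    lower_bound: float = -np.inf,
    upper_bound: float = np.inf,
) -> PowerResult:
    """Monte-Carlo two-group ANOVA study at published mean ± SD parameters.

    Each replicate draws two truncated-normal groups of size ``n`` and runs
    the one-way ANOVA; the result reports the fraction of replicates with
    p < alpha and the median p-value. With identical group parameters the
    rejection rate calibrates to alpha (type-I error).
    """
    if sd_a <= 0 or sd_b <= 0:
        raise ParameterError("group SDs must be positive")
    if reps < 100:
        raise ParameterError("reps must be >= 100")
    if not (0 < alpha < 1):
        raise ParameterError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pvals = np.empty(reps, dtype=np.float64)
    for r in range(reps):
        a = sample_group_measurements(mean_a, sd_a, n, lower_bound, upper_bound, rng)
        b = sample_group_measurements(mean_b, sd_b, n, lower_bound, upper_bound, rng)
        pvals[r] = anova_oneway(a, b).p_value
    return PowerResult(
        rejection_rate=float((pvals < alpha).mean()),
        median_p=float(np.median(pvals)),
        reps=reps,
    )


def tg_normalize(od_450: float, blank_od: float, cell_count: float) -> float:
    """Cell-number-normalized enzymatic activity: (OD₄₅₀ − blank)/cells × 10⁴.

    The 10⁴-cell scaling is a reporting convention giving readable
    magnitudes. A signal below blank is clamped to zero with a warning.
    """
    if cell_count <= 0:
        raise ParameterError("cell_count must be positive")
    if blank_od < 0:
        raise ParameterError("blank_od must be nonnegative")
    signal = od_450 - blank_od
    if signal < 0:
        warnings.warn("OD below blank; clamping normalized activity to 0",
                      stacklevel=2)
        signal = 0.0
    return signal / cell_count * 1e4


def fold_change(summary_a: GroupSummary, summary_b: GroupSummary) -> float:
    """Ratio of group means, A relative to B."""
    if summary_b.mean <= 0:
        raise ParameterError("reference group mean must be positive")
    return summary_a.mean / summary_b.mean
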