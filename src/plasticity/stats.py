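"""Nonparametric bootstrap inference and a façade over standard tests.

Fractions of active (or otherwise labelled) units are compared by resampling
units with replacement, 10,000 iterations by default, with percentile
confidence intervals at the 95% level. Two-group differences are tested by
independent within-group resampling of the fraction difference, with a
two-sided p-value floored at 2/n_iterations. The resampling unit (neuron,
dendrite, FOV, brain) is the caller's choice of rows.

Classic hypothesis tests (Friedman, repeated-measures ANOVA, Dunnett, Tukey,
t, Mann–Whitney, Kolmogorov–Smirnov) are delegated to scipy/statsmodels
routines; this module adds no bespoke test math.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BootstrapResult",
    "bootstrap_fraction_ci",
    "bootstrap_difference_test",
    "standard_test",
]


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_iterations: int
    level: float
    resample_unit: str
    seed: int
    p_value: float | None = None


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(list(labels), dtype=float)
    if arr.size == 0:
        raise ValueError("empty label vector")
    return arr


def bootstrap_fraction_ci(
    labels,
    n_iterations: int = 10000,
    level: float = 0.95,
    seed: int = 0,
    resample_unit: str = "neuron",
) -> BootstrapResult:
    """Percentile bootstrap CI for the fraction of positive units.

    Units are resampled with replacement ``n_iterations`` times; the CI is
    the ``(1-level)/2`` and ``1-(1-level)/2`` percentiles of the resampled
    fractions. The point estimate is the plug-in (observed) fraction.
    """
    x = _as_binary(labels)
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    n = x.size
    idx = rng.integers(0, n, size=(n_iterations, n))
    boot = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return BootstrapResult(
        estimate=float(x.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_iterations=n_iterations,
        level=level,
        resample_unit=resample_unit,
        seed=seed,
    )


def bootstrap_difference_test(
    labels_a,
    labels_b,
    n_iterations: int = 10000,
    level: float = 0.95,
    seed: int = 0,
    resample_unit: str = "neuron",
) -> BootstrapResult:
    """Bootstrap test of fraction(A) − fraction(B).

    Groups are resampled independently; the two-sided p-value is
    ``2 * min(P(diff <= 0), P(diff >= 0))`` over the bootstrap distribution,
    clipped to ``[2/n_iterations, 1]``.
    """
    a, b = _as_binary(labels_a), _as_binary(labels_b)
    rng = np.random.default_rng(seed)
    na, nb = a.size, b.size
    boot_a = a[rng.integers(0, na, size=(n_iterations, na))].mean(axis=1)
    boot_b = b[rng.integers(0, nb, size=(n_iterations, nb))].mean(axis=1)
    diff = boot_a - boot_b
    p_le = np.mean(diff <= 0)
    p_ge = np.mean(diff >= 0)
    p = float(np.clip(2.0 * min(p_le, p_ge), 2.0 / n_iterations, 1.0))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diff, [alpha, 1.0 - alpha])
    return BootstrapResult(
        estimate=float(a.mean() - b.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_iterations=n_iterations,
        level=level,
        resample_unit=resample_unit,
        seed=seed,
        p_value=p,
    )


def standard_test(name: str, data, **kwargs) -> dict:
    """Delegate a named classic test to an established routine.

    ``data`` is a list of sample arrays for two-/k-sample tests, or a tidy
    DataFrame with columns (subject, condition, value) — plus a second
    within factor for the two-way design — for repeated-measures ANOVA.
    Returns a dict with ``statistic``, ``p_value`` and the delegated
    routine's identity.
    """
    if name == "friedman":
        samples = [np.asarray(s, dtype=float) for s in data]
        if all(np.array_equal(samples[0], s) for s in samples[1:]):
            # fully tied conditions: no evidence of any difference
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.friedmanchisquare(*samples)
        routine = "scipy.stats.friedmanchisquare"
    elif name in ("rm_anova_oneway", "rm_anova_twoway"):
        from statsmodels.stats.anova import AnovaRM

        df = data
        if not isinstance(df, pd.DataFrame):
            raise ValueError(
                "repeated-measures ANOVA expects a DataFrame with columns "
                "(subject, condition, value[, condition2])"
            )
        within = ["condition"] if name == "rm_anova_oneway" else ["condition", "condition2"]
        missing = {c for c in ["subject", "value", *within]} - set(df.columns)
        if missing:
            raise ValueError(f"repeated-measures ANOVA data missing columns: {sorted(missing)}")
        res = AnovaRM(df, depvar="value", subject="subject", within=within).fit()
        stat = float(res.anova_table["F Value"].iloc[0])
        p = float(res.anova_table["Pr > F"].iloc[0])
        routine = "statsmodels.stats.anova.AnovaRM"
    elif name == "anova_dunnett":
        control = kwargs.pop("control", data[0])
        res = sps.dunnett(*data[1:], control=np.asarray(control), **kwargs)
        stat = [float(s) for s in np.atleast_1d(res.statistic)]
        p = [float(v) for v in np.atleast_1d(res.pvalue)]
        routine = "scipy.stats.dunnett"
    elif name == "tukey":
        res = sps.tukey_hsd(*data)
        stat = res.statistic.tolist()
        p = res.pvalue.tolist()
        routine = "scipy.stats.tukey_hsd"
    elif name == "t_two_sided":
        stat, p = sps.ttest_ind(data[0], data[1])
        routine = "scipy.stats.ttest_ind"
    elif name == "mann_whitney":
        stat, p = sps.mannwhitneyu(data[0], data[1], alternative="two-sided")
        routine = "scipy.stats.mannwhitneyu"
    elif name == "ks":
        stat, p = sps.ks_2samp(data[0], data[1])
        routine = "scipy.stats.ks_2samp"
    else:
        raise ValueError(f"unknown test name {name!r}")
    to_f = lambda v: v if isinstance(v, list) else float(v)  # noqa: E731
    return {"test": name, "routine": routine, "statistic": to_f(stat), "p_value": to_f(p)}
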