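"""Normality screening and Welch-Satterthwaite breed comparison.

Each metric is screened per group with the Shapiro-Wilk test (p >= 0.05
taken as consistent with normality) and the two breeds are compared with
Welch's unequal-variance t-test using Satterthwaite's approximate degrees
of freedom::

    t  = (m_a - m_b) / sqrt(s2_a/n_a + s2_b/n_b)
    df = (s2_a/n_a + s2_b/n_b)^2 /
         [ (s2_a/n_a)^2/(n_a-1) + (s2_b/n_b)^2/(n_b-1) ]

with a two-tailed p from the t distribution and significance at
p <= 0.05.  Following the source protocol, a failed normality screen is
recorded (with a warning) but does not change the test, and no
multiple-comparison correction is applied by default; Holm adjustment is
available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonRow",
    "shapiro_wilk",
    "welch_t",
    "breed_comparison",
    "format_mean_sd",
]

ALPHA = 0.05


@dataclass
class ComparisonRow:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    summary_a: str
    summary_b: str
    shapiro_w_a: float
    shapiro_p_a: float
    shapiro_w_b: float
    shapiro_p_b: float
    normal_a: bool
    normal_b: bool
    t: float
    df: float
    p: float
    significant: bool


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk statistic W and p-value for one sample.

    Requires 3 <= n <= 5000 and non-zero variance.  Normal verdict is
    ``p >= 0.05``.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs at least 3 observations, got {x.size}")
    if x.size > 5000:
        raise ValueError(f"Shapiro-Wilk is unreliable above n=5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample (zero variance)")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t with Satterthwaite df and two-tailed p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test needs at least 2 observations per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


def format_mean_sd(values, decimals: int = 1) -> str:
    """Mean ± SD string at the reporting granularity of the study tables."""
    x = np.asarray(values, dtype=float)
    return f"{x.mean():.{decimals}f} ± {x.std(ddof=1):.{decimals}f}"


def breed_comparison(
    metrics: pd.DataFrame,
    group_col: str = "breed",
    metric_col: str = "metric",
    value_col: str = "value",
    alpha: float = ALPHA,
    holm: bool = False,
) -> pd.DataFrame:
    """One Welch comparison row per metric between the two groups.

    ``metrics`` is a long table of per-subject values.  Each metric must
    be present in both groups with >= 2 subjects.  No multiplicity
    adjustment is applied unless ``holm=True`` (adds ``p_holm`` and bases
    the significance flag on it).
    """
    groups = sorted(metrics[group_col].unique().tolist())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups in {group_col!r}, got {groups}")
    ga, gb = groups
    rows: list[ComparisonRow] = []
    for metric in sorted(metrics[metric_col].unique().tolist()):
        sub = metrics[metrics[metric_col] == metric]
        xa = sub.loc[sub[group_col] == ga, value_col].to_numpy(dtype=float)
        xb = sub.loc[sub[group_col] == gb, value_col].to_numpy(dtype=float)
        if xa.size < 2 or xb.size < 2:
            raise ValueError(
                f"metric {metric!r} needs >= 2 subjects per group "
                f"(got {ga}: {xa.size}, {gb}: {xb.size})"
            )
        w_a = p_a = w_b = p_b = float("nan")
        try:
            w_a, p_a = shapiro_wilk(xa)
            w_b, p_b = shapiro_wilk(xb)
        except ValueError:
            pass  # screen not computable (tiny or constant sample); Welch still runs
        normal_a = bool(p_a >= alpha) if np.isfinite(p_a) else False
        normal_b = bool(p_b >= alpha) if np.isfinite(p_b) else False
        if np.isfinite(p_a) and not (normal_a and normal_b):
            warnings.warn(
                f"metric {metric!r}: Shapiro-Wilk rejects normality "
                f"({ga}: p={p_a:.3g}, {gb}: p={p_b:.3g}); Welch's test run regardless",
                stacklevel=2,
            )
        t, df, p = welch_t(xa, xb)
        rows.append(
            ComparisonRow(
                metric=metric,
                group_a=ga,
                group_b=gb,
                n_a=int(xa.size),
                n_b=int(xb.size),
                mean_a=float(xa.mean()),
                sd_a=float(xa.std(ddof=1)),
                mean_b=float(xb.mean()),
                sd_b=float(xb.std(ddof=1)),
                summary_a=format_mean_sd(xa),
                summary_b=format_mean_sd(xb),
                shapiro_w_a=w_a,
                shapiro_p_a=p_a,
                shapiro_w_b=w_b,
                shapiro_p_b=p_b,
                normal_a=normal_a,
                normal_b=normal_b,
                t=t,
                df=df,
                p=p,
                significant=bool(p <= alpha),
            )
        )
    out = pd.DataFrame([r.__dict__ for r in rows])
    if holm:
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
        out["significant"] = out["p_holm"] <= alpha
    return out
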