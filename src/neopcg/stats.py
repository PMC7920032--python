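"""Cohort-level nonparametric and parametric statistics.

Implemented from first principles so that small-sample exactness (the
target cohort is 9 vs 9) is verifiable against enumeration oracles:

* **Mann-Whitney U** with midranks; exact two-sided p by complete
  enumeration of the rank-sum null distribution (a subset-sum dynamic
  program equivalent to enumerating all C(n1+n2, n1) group labelings)
  for n1+n2 <= 20, normal approximation with tie correction beyond.
* **Spearman rank correlation**; exact permutation p for n <= 8,
  t-approximation otherwise.
* Ordinary least-squares **linear regression** (slope/intercept).
* **Paired t-test**.

Two-sided p-values throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

__all__ = [
    "mann_whitney_exact",
    "spearman",
    "linear_regression",
    "paired_t",
    "CohortTable",
    "CohortReport",
    "run_cohort_analysis",
    "EXACT_LIMIT",
]

EXACT_LIMIT = 20       # exact Mann-Whitney up to this combined n
SPEARMAN_EXACT_N = 8   # exact permutation p up to this n


def _rank_sum_distribution(ranks2: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of the group-1 rank sum over all C(n, n1) labelings.

    Works on ranks doubled to integers (midranks are multiples of 1/2).
    Returns (support_of_2*ranksum, counts).  The dynamic program counts,
    for each k and each achievable sum s, the number of k-subsets of the
    doubled ranks summing to s — identical to full enumeration.
    """
    total = int(ranks2.sum())
    # counts[k, s] = number of k-subsets with doubled-rank sum s
    counts = np.zeros((n1 + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        # iterate k downward so each rank enters a subset at most once
        for k in range(n1, 0, -1):
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    support = np.arange(total + 1)
    return support, counts[n1]


def mann_whitney_exact(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with an exact two-sided p for small samples.

    U is computed from midrank sums.  For n1+n2 <= EXACT_LIMIT the
    two-sided p is the exact null probability of a U at least as far
    from its mean n1*n2/2 as the observed one, over all C(n1+n2, n1)
    equally likely group labelings (ties handled natively by
    enumerating the observed midranks).  Larger samples use the normal
    approximation with tie-corrected variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    u = max(u1, n1 * n2 - u1)  # report the larger U

    if n1 + n2 <= EXACT_LIMIT:
        ranks2 = np.rint(2 * ranks).astype(int)
        support, counts = _rank_sum_distribution(ranks2, n1)
        total_count = counts.sum()
        # doubled rank sum -> doubled U (shift by n1(n1+1))
        u_support = support - n1 * (n1 + 1)
        dev = np.abs(u_support - 2 * mu)
        obs_dev = abs(2 * u1 - 2 * mu)
        p = counts[dev >= obs_dev - 1e-9].sum() / total_count
    else:
        tie_counts = np.unique(pooled, return_counts=True)[1]
        n = n1 + n2
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return u, 1.0
        z = (abs(u1 - mu) - 0.5) / math.sqrt(var)  # continuity correction
        p = 2.0 * 0.5 * math.erfc(max(z, 0.0) / math.sqrt(2))
    return float(u), float(min(p, 1.0))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float((xc**2).sum()) * float((yc**2).sum()))
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    return float((xc * yc).sum() / denom)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midranks.

    rho is the product-moment correlation of the midranks.  The
    two-sided p is exact (complete permutation enumeration) for
    n <= SPEARMAN_EXACT_N, otherwise from the t-approximation
    t = rho sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")
    rx, ry = rankdata(x), rankdata(y)
    rho = _pearson(rx, ry)

    if n <= SPEARMAN_EXACT_N:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _pearson(rx, ry[list(perm)])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = float(np.finfo(float).tiny)
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * t_dist.sf(abs(t), df=n - 2))
    return float(rho), float(max(min(p, 1.0), np.finfo(float).tiny))


def linear_regression(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least squares; returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 equal-length values")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("constant x: regression undefined")
    slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    return slope, float(y.mean() - slope * x.mean())


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Paired t-test: t = mean(d) / (sd(d)/sqrt(n)), d = x - y, df = n-1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 paired values")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValueError("zero-variance differences: t undefined")
    n = len(d)
    t = float(np.mean(d)) / (sd / math.sqrt(n))
    p = float(2.0 * t_dist.sf(abs(t), df=n - 1))
    return t, max(p, np.finfo(float).tiny)


@dataclass
class CohortTable:
    """Per-subject SNR_sys on both sensors plus group labels.

    Optionally carries per-position vitals (heart rate, SpO2) for the
    paired positional comparisons.
    """

    frame: pd.DataFrame  # columns: subject_id, group, snr_sys_ps, snr_sys_steth, ...

    REQUIRED = ("subject_id", "group", "snr_sys_ps", "snr_sys_steth")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"CohortTable missing columns: {missing}")
        ids = self.frame["subject_id"]
        if ids.duplicated().any():
            raise ValueError("subject_ids must be unique")

    def group_values(self, group: str, column: str = "snr_sys_ps") -> np.ndarray:
        return self.frame.loc[self.frame["group"] == group, column].to_numpy(float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))


@dataclass
class CohortReport:
    group_summary: dict          # per group: median, min, max, n
    mann_whitney: tuple[float, float]        # (U, p)
    spearman: tuple[float, float]            # (rho, p)
    regression: tuple[float, float]          # (slope, intercept)
    paired_tests: list[tuple[str, float, float]] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def group_difference_significant(self) -> bool:
        return self.mann_whitney[1] < self.alpha

    @property
    def correlation_significant(self) -> bool:
        return self.spearman[1] < self.alpha

    def to_dict(self) -> dict:
        return {
            "group_summary": self.group_summary,
            "mann_whitney": {"U": self.mann_whitney[0], "p": self.mann_whitney[1],
                             "significant": self.group_difference_significant},
            "spearman": {"rho": self.spearman[0], "p": self.spearman[1],
                         "significant": self.correlation_significant},
            "regression": {"slope": self.regression[0], "intercept": self.regression[1]},
            "paired_tests": [
                {"label": lbl, "t": t, "p": p, "significant": p < self.alpha}
                for lbl, t, p in self.paired_tests
            ],
            "alpha": self.alpha,
        }

    def summary(self) -> str:
        lines = ["Cohort analysis"]
        for g, s in self.group_summary.items():
            lines.append(
                f"  {g}: n={s['n']}, median SNR_sys(PS)={s['median']:.2f} dB, "
                f"range [{s['min']:.2f}, {s['max']:.2f}]"
            )
        u, p = self.mann_whitney
        lines.append(f"  Mann-Whitney U={u:g}, two-sided p={p:.3g}"
                     f"{' *' if p < self.alpha else ''}")
        rho, sp = self.spearman
        lines.append(f"  Spearman rho={rho:.3f}, p={sp:.3g}"
                     f"{' *' if sp < self.alpha else ''}")
        slope, intercept = self.regression
        lines.append(f"  Regression: PS = {slope:.3f} x stethoscope + {intercept:.3f}")
        for lbl, t, p in self.paired_tests:
            lines.append(f"  Paired t ({lbl}): t={t:.3f}, p={p:.3g}")
        return "\n".join(lines)


def run_cohort_analysis(table: CohortTable, alpha: float = 0.05) -> CohortReport:
    """Group comparison, sensor agreement and optional paired vitals.

    Mann-Whitney compares SNR_sys(PS) between the CHD and control
    groups; Spearman and OLS relate SNR_sys(PS) to SNR_sys(stethoscope)
    across all subjects; columns named ``<vital>_supine`` /
    ``<vital>_prone`` trigger paired t-tests.
    """
    df = table.frame
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need two non-empty groups for comparison")
    chd = table.group_values("CHD")
    ctl = table.group_values("control")
    if len(chd) < 2 or len(ctl) < 2:
        raise ValueError("need >= 2 subjects per group")

    summary = {}
    for g in ("CHD", "control"):
        v = table.group_values(g)
        summary[g] = {"n": int(len(v)), "median": float(np.median(v)),
                      "min": float(v.min()), "max": float(v.max())}

    mw = mann_whitney_exact(chd, ctl)
    steth = df["snr_sys_steth"].to_numpy(float)
    ps = df["snr_sys_ps"].to_numpy(float)
    sp = spearman(steth, ps)
    reg = linear_regression(steth, ps)

    paired = []
    for col in df.columns:
        if col.endswith("_supine"):
            base = col[: -len("_supine")]
            other = f"{base}_prone"
            if other in df.columns:
                t, p = paired_t(df[col].to_numpy(float), df[other].to_numpy(float))
                paired.append((base, t, p))

    return CohortReport(summary, mw, sp, reg, paired, alpha)
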