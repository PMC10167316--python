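"""Group-difference statistics with false-discovery-rate control.

Independent two-sample t-tests (pooled-variance by default, Welch
optional), a t-test from printed summary statistics, the 2x2 chi-square
test of homogeneity (without continuity correction by default), the
Benjamini-Hochberg step-up procedure, and channel-wise group testing of a
feature table with topographic masking (non-significant channels get a
masked t of exactly zero, the convention used for topographic maps).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable
from .montage import Montage

__all__ = [
    "TTestResult",
    "Chi2Result",
    "FDRResult",
    "GroupStatsResult",
    "ttest_independent",
    "ttest_from_summary",
    "chi2_2x2",
    "fdr_bh",
    "channelwise_group_test",
    "export_topography",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value out of [0, 1]")


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class FDRResult:
    """Benjamini-Hochberg outcome at target level q."""

    q: float
    p_threshold: float
    reject: np.ndarray  # bool per hypothesis, input order

    @property
    def n_rejected(self) -> int:
        return int(self.reject.sum())


@dataclass(frozen=True)
class GroupStatsResult:
    """Per-feature t-tests with BH-FDR masking over the feature family."""

    feature_names: tuple[str, ...]
    t: np.ndarray
    p: np.ndarray
    fdr: FDRResult

    @property
    def masked_t(self) -> np.ndarray:
        return np.where(self.fdr.reject, self.t, 0.0)

    @property
    def significant(self) -> list[str]:
        return [n for n, r in zip(self.feature_names, self.fdr.reject) if r]


def ttest_independent(
    sample_a: Sequence[float], sample_b: Sequence[float], variant: str = "pooled"
) -> TTestResult:
    """Two-sided independent t-test; t's sign follows mean(a) - mean(b)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        raise ValueError("undefined statistic: both samples constant and equal")
    if variant == "pooled":
        res = stats.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    elif variant == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def ttest_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TTestResult:
    """Pooled-variance t-test from printed means/SDs, df = n1 + n2 - 2."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return TTestResult(t=float(res.statistic), df=float(n1 + n2 - 2), p=float(res.pvalue))


def chi2_2x2(table: Sequence[Sequence[int]], correction: str = "none") -> Chi2Result:
    """Chi-square test of homogeneity on a 2x2 count table.

    ``correction='none'`` (default) is the plain Pearson statistic
    sum (O-E)^2 / E; ``'yates'`` applies the continuity correction.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    if correction not in ("none", "yates"):
        raise ValueError(f"unknown correction {correction!r}")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=(correction == "yates"))
    return Chi2Result(chi2=float(chi2), df=int(df), p=float(p))


def fdr_bh(pvalues: Sequence[float], q: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up over a family of p-values.

    Sort ascending, find the largest i with p_(i) <= i*q/m, reject every
    hypothesis with p <= p_(i).  The threshold is 0 when nothing is
    rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = np.arange(1, m + 1) * q / m
    passing = np.flatnonzero(sorted_p <= crit)
    if passing.size == 0:
        return FDRResult(q=q, p_threshold=0.0, reject=np.zeros(m, dtype=bool))
    thr = float(sorted_p[passing[-1]])
    return FDRResult(q=q, p_threshold=thr, reject=p <= thr)


def channelwise_group_test(
    ft: FeatureTable, q: float = 0.05, variant: str = "pooled"
) -> GroupStatsResult:
    """Per-feature high-vs-low t-tests with BH-FDR across the feature family."""
    groups = set(ft.groups)
    if not {"high", "low"} <= groups:
        raise ValueError("feature table must contain both groups")
    hi = ft.values[ft.groups == "high"].to_numpy()
    lo = ft.values[ft.groups == "low"].to_numpy()
    if hi.shape[0] < 2 or lo.shape[0] < 2:
        raise ValueError("each group needs n >= 2")
    ts, ps = [], []
    for j in range(hi.shape[1]):
        r = ttest_independent(hi[:, j], lo[:, j], variant=variant)
        ts.append(r.t)
        ps.append(r.p)
    t = np.array(ts)
    p = np.array(ps)
    return GroupStatsResult(
        feature_names=tuple(ft.descriptors),
        t=t,
        p=p,
        fdr=fdr_bh(p, q),
    )


def _channel_of(descriptor: str) -> str:
    return descriptor.rsplit("|", 1)[-1]


def export_topography(
    gsr: GroupStatsResult, montage: Montage, path: str | Path, render: bool = False
) -> Path:
    """Write the per-channel statistic table (and optionally a rendered map).

    Columns: channel, x, y, t, p, masked_t, rejected — channel order follows
    the montage.  ``render=True`` additionally writes ``<path>.png`` with a
    simple scatter topography (requires matplotlib).
    """
    path = Path(path)
    by_channel = { _channel_of(n): i for i, n in enumerate(gsr.feature_names) }
    unknown = [c for c in by_channel if c not in montage.channel_names]
    if unknown:
        raise KeyError(f"channels not in montage: {unknown}")
    rows = []
    masked = gsr.masked_t
    for name in montage.channel_names:
        if name not in by_channel:
            continue
        i = by_channel[name]
        x, y = montage.position(name)
        rows.append(
            {
                "channel": name,
                "x": x,
                "y": y,
                "t": gsr.t[i],
                "p": gsr.p[i],
                "masked_t": masked[i],
                "rejected": bool(gsr.fdr.reject[i]),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    if render:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        sc = ax.scatter(df["x"], df["y"], c=df["masked_t"], cmap="RdBu_r", s=200,
                        edgecolors=np.where(df["rejected"], "k", "0.6"))
        for _, r in df.iterrows():
            ax.annotate(r["channel"], (r["x"], r["y"]), fontsize=6, ha="center", va="center")
        circ = plt.Circle((0, 0), 1.0, fill=False, color="k")
        ax.add_patch(circ)
        ax.set_aspect("equal")
        ax.axis("off")
        fig.colorbar(sc, ax=ax, label="masked t")
        fig.savefig(path.with_suffix(path.suffix + ".png"), dpi=120, bbox_inches="tight")
        plt.close(fig)
    return path
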