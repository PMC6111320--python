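"""Group-level statistics: grand-average curves, paired t-tests on the
protocol's comparison windows, and Pearson correlations with Fisher-z
95% confidence intervals.

Individual marker series are z-scored over their region-of-interest
extent and smoothed with a centered 10-sample moving average (window
shrinks at the edges) before the grand mean and the standard error of
the mean are taken across subjects.  Correlations are computed between
the smoothed grand-average curves with n = number of epoch pairs;
no multiple-testing correction is applied (one test per comparison at
alpha = 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .session import EventTimeline

__all__ = [
    "GroupCurve",
    "TTestResult",
    "CorrelationResult",
    "zscore_smooth",
    "grand_average",
    "paired_ttest",
    "comparison_windows",
    "pearson_ci",
    "marker_correlation_table",
    "group_curves_table",
    "window_comparison_tests",
]

SMOOTH_WINDOW = 10  # samples (2-s epochs)


@dataclass
class GroupCurve:
    """Grand mean and SEM across subjects, per epoch."""

    mean: np.ndarray
    sem: np.ndarray
    n_subjects: int


@dataclass
class TTestResult:
    t: float
    p: float
    alpha: float
    significant: bool
    degenerate: bool = False
    window_a: str = ""
    window_b: str = ""


@dataclass
class CorrelationResult:
    pcc: float
    n: int
    ci_low: float
    ci_up: float


def zscore_smooth(series: np.ndarray) -> np.ndarray:
    """Z-score a series over its full extent, then apply a centered
    10-sample moving average with window shrinkage at the edges."""
    x = np.asarray(series, float)
    sd = x.std()
    if sd < 1e-12 * (1.0 + np.abs(x).max(initial=0.0)):
        warnings.warn("constant series z-scored to all-zeros")
        z = np.zeros_like(x)
    else:
        z = (x - x.mean()) / sd
    return (
        pd.Series(z).rolling(SMOOTH_WINDOW, center=True, min_periods=1).mean().to_numpy()
    )


def grand_average(per_subject_series: list[np.ndarray]) -> GroupCurve:
    """Grand-average a set of aligned per-subject marker series."""
    if len(per_subject_series) < 2:
        raise ValueError("grand average needs at least 2 subjects")
    lengths = {len(s) for s in per_subject_series}
    if len(lengths) != 1:
        raise ValueError(f"series lengths differ: {sorted(lengths)}")
    smoothed = np.vstack([zscore_smooth(s) for s in per_subject_series])
    return GroupCurve(
        mean=smoothed.mean(axis=0),
        sem=smoothed.std(axis=0, ddof=1) / np.sqrt(smoothed.shape[0]),
        n_subjects=smoothed.shape[0],
    )


def paired_ttest(a, b, alpha: float = 0.05) -> TTestResult:
    """Classical two-sided paired-sample t-test on the differences."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t-test needs two equal-length arrays of size >= 2")
    d = a - b
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return TTestResult(0.0, 1.0, alpha, False)
        # identical nonzero differences: zero variance, infinitely strong effect
        return TTestResult(math_inf_sign(d[0]), 0.0, alpha, True, degenerate=True)
    t, p = spstats.ttest_rel(a, b)
    return TTestResult(float(t), float(p), alpha, bool(p < alpha))


def math_inf_sign(x: float) -> float:
    return float(np.inf if x > 0 else -np.inf)


def comparison_windows(timeline: EventTimeline) -> dict[str, tuple[float, float]]:
    """The three 30-s value windows compared by the paired tests: last
    30 s of RS1, last 30 s of the stress session, and the second-to-last
    30 s of the relaxation session."""
    t = timeline
    wins = {
        "rs1_end": (t.rs1_end - 30.0, t.rs1_end),
        "mist_end": (t.mist_end - 30.0, t.mist_end),
        "relax_late": (t.relax_end - 60.0, t.relax_end - 30.0),
    }
    if t.relax_end - t.relax_start < 60.0:
        raise ValueError("relaxation session shorter than 60 s; comparison windows undefined")
    for name, (s, e) in wins.items():
        if s < 0:
            raise ValueError(f"comparison window {name} starts before the recording")
    return wins


def processed_comparison_windows(timeline: EventTimeline) -> dict[str, tuple[float, float]]:
    """Comparison windows restricted to epochs the marker pipeline
    actually processes.

    Only the central minute of each resting-state block enters the
    regions of interest, so the literal last 30 s of RS1 holds no
    processed epochs; the RS1 window is therefore the last 30 s of the
    processed resting-state segment.  The stress and relaxation windows
    lie inside the regions of interest and are unchanged."""
    wins = dict(comparison_windows(timeline))
    t = timeline
    wins["rs1_end"] = (t.rs1_start + 60.0, t.rs1_start + 90.0)
    return wins


def pearson_ci(
    x=None, y=None, *, r: float | None = None, n: int | None = None
) -> CorrelationResult:
    """Pearson correlation with a 95% Fisher-z confidence interval.

    Either pass two paired samples, or a precomputed coefficient ``r``
    with its pair count ``n``.  CI = tanh(atanh(r) +/- 1.96/sqrt(n-3)).
    """
    if r is None:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if x.shape != y.shape:
            raise ValueError("x and y must be paired")
        n = x.size
        if n < 4:
            raise ValueError(f"need n >= 4 pairs, got {n}")
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        if n is None:
            raise ValueError("n is required when r is given")
        if n < 4:
            raise ValueError(f"need n >= 4, got {n}")
    if abs(r) >= 1.0:
        return CorrelationResult(float(r), int(n), float(r), float(r))
    h = 1.96 / np.sqrt(n - 3)
    z = np.arctanh(r)
    return CorrelationResult(float(r), int(n), float(np.tanh(z - h)), float(np.tanh(z + h)))


# ---------------------------------------------------------------------------
# pipeline-level helpers operating on marker tables


def _per_subject_matrix(markers: pd.DataFrame, column: str) -> list[np.ndarray]:
    out = [
        g.sort_values("epoch_start_s")[column].to_numpy()
        for _, g in markers.groupby("subject_id", sort=True)
    ]
    return out


def marker_correlation_table(markers: pd.DataFrame) -> pd.DataFrame:
    """Pairwise correlations between smoothed grand-averaged marker
    curves, with 95% CIs; mirrors the shape PCC / CI low / CI up."""
    curves = {
        m: grand_average(_per_subject_matrix(markers, m)).mean for m in ("RG", "HR", "TA", "SC")
    }
    rows = []
    names = list(curves)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = pearson_ci(curves[a], curves[b])
            rows.append(
                {"pair": f"{a}, {b}", "pcc": res.pcc, "n": res.n,
                 "ci_low": res.ci_low, "ci_up": res.ci_up}
            )
    return pd.DataFrame(rows)


def group_curves_table(markers: pd.DataFrame) -> pd.DataFrame:
    """Grand-average curve (mean and SEM per epoch) for every marker,
    in long format: marker, epoch_start_s, mean, sem."""
    frames = []
    starts = np.sort(markers[markers.subject_id == markers.subject_id.iloc[0]]
                     ["epoch_start_s"].to_numpy())
    for m in ("RG", "HR", "TA", "SC"):
        curve = grand_average(_per_subject_matrix(markers, m))
        frames.append(pd.DataFrame(
            {"marker": m, "epoch_start_s": starts, "mean": curve.mean, "sem": curve.sem}
        ))
    return pd.concat(frames, ignore_index=True)


def window_comparison_tests(
    markers: pd.DataFrame, timeline: EventTimeline, alpha: float = 0.05
) -> pd.DataFrame:
    """Paired t-tests (across subjects, on per-subject window means) of
    every marker between the three comparison windows (restricted to
    processed epochs, see :func:`processed_comparison_windows`)."""
    wins = processed_comparison_windows(timeline)
    rows = []
    for marker in ("RG", "HR", "TA", "SC"):
        means = {}
        for wname, (s, e) in wins.items():
            sel = (markers["epoch_start_s"] >= s) & (markers["epoch_start_s"] < e)
            sub = markers[sel].groupby("subject_id", sort=True)[marker].mean()
            means[wname] = sub.to_numpy()
        for wa, wb in (("rs1_end", "mist_end"), ("mist_end", "relax_late"),
                       ("rs1_end", "relax_late")):
            res = paired_ttest(means[wa], means[wb], alpha=alpha)
            rows.append(
                {"marker": marker, "window_a": wa, "window_b": wb,
                 "t": res.t, "p": res.p, "significant": res.significant}
            )
    return pd.DataFrame(rows)


def spsl_tests(spsl_triples: list[tuple[int, int, int]], alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-tests of the self-perceived stress ratings between the
    three question points T1/T2/T3."""
    arr = np.asarray(spsl_triples, float)
    labels = ("T1", "T2", "T3")
    rows = []
    for i, j in ((0, 1), (1, 2), (0, 2)):
        res = paired_ttest(arr[:, i], arr[:, j], alpha=alpha)
        rows.append(
            {"a": labels[i], "b": labels[j], "t": res.t, "p": res.p,
             "significant": res.significant, "degenerate": res.degenerate}
        )
    return pd.DataFrame(rows)
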