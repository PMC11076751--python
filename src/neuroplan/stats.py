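"""Paired pre/post comparison and descriptive summaries.

The pipeline compares each accuracy metric between Accuracy Assessment-1
(post-MRI planning) and Accuracy Assessment-2 (post-3D-model planning) on
the same participants: a paired t-test for continuous metrics (mm, mm², %)
and the Wilcoxon matched-pairs signed-rank test for the ordinal 0-4 scores.
Descriptive summaries are mean ± SD (parametric) or median [Q1–Q3]
(nonparametric, linear-interpolation quartiles); Likert feedback items
(1-10) are summarized as median [IQR].

The signed-rank test is implemented here rather than delegated: zero
differences are dropped before ranking (their count is reported), the exact
null distribution is used for n <= 25 — computed by dynamic programming on
doubled midranks, so ties are handled exactly — and a normal approximation
with tie correction and continuity correction is used for larger n. No
multiple-testing correction is applied across metrics; results carry a note
to that effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AlignmentError, InvalidInputError

__all__ = [
    "ALPHA",
    "PairedSample",
    "Summary",
    "ComparisonResult",
    "summarize",
    "paired_compare",
    "stratified_compare",
    "make_paired_sample",
    "compare_table",
    "likert_summary",
]

#: Significance level used throughout.
ALPHA = 0.05

#: Metrics treated as ordinal (Wilcoxon under method="auto").
ORDINAL_SUFFIX = "_points"


@dataclass(frozen=True)
class Summary:
    """Descriptive summary of one sample."""

    kind: str  # parametric | nonparametric
    n: int
    center: float  # mean or median
    spread: tuple  # (sd,) or (q1, q3)
    flagged: str | None = None

    def __str__(self) -> str:
        if self.kind == "parametric":
            sd = self.spread[0]
            sd_s = "undefined" if np.isnan(sd) else f"{sd:.2f}"
            return f"{self.center:.2f} ± {sd_s}"
        q1, q3 = self.spread
        return f"{_fmt(self.center)} [{_fmt(q1)}–{_fmt(q3)}]"


def _fmt(x: float) -> str:
    return f"{x:g}"


def summarize(values: Sequence[float], kind: str = "parametric") -> Summary:
    """Mean ± SD (ddof=1) or median [Q1–Q3] with interpolated quartiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidInputError("cannot summarize an empty sample")
    if np.any(~np.isfinite(v)):
        raise InvalidInputError("sample contains non-finite values")
    if kind == "parametric":
        if v.size == 1:
            return Summary("parametric", 1, float(v[0]), (np.nan,), flagged="single-value: SD undefined")
        return Summary("parametric", v.size, float(np.mean(v)), (float(np.std(v, ddof=1)),))
    if kind == "nonparametric":
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
        return Summary("nonparametric", v.size, float(med), (float(q1), float(q3)))
    raise InvalidInputError(f"unknown summary kind {kind!r}")


@dataclass(frozen=True)
class PairedSample:
    """Aligned pre/post values of one metric for one set of participants."""

    ids: tuple
    values_aa1: np.ndarray
    values_aa2: np.ndarray
    metric: str = ""
    units: str = ""
    groups: tuple | None = None
    kind: str = "continuous"  # continuous | ordinal

    def __post_init__(self) -> None:
        a = np.asarray(self.values_aa1, dtype=float)
        b = np.asarray(self.values_aa2, dtype=float)
        object.__setattr__(self, "values_aa1", a)
        object.__setattr__(self, "values_aa2", b)
        object.__setattr__(self, "ids", tuple(self.ids))
        if len(self.ids) != a.size or a.size != b.size:
            raise AlignmentError("paired sample vectors must be aligned with ids")
        if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            raise AlignmentError("paired sample contains missing values")

    @property
    def n(self) -> int:
        return self.values_aa1.size


@dataclass(frozen=True)
class ComparisonResult:
    """Paired pre/post test result for one metric."""

    metric: str
    units: str
    n: int
    summary_aa1: Summary
    summary_aa2: Summary
    test: str
    statistic: float
    p_value: float
    significant: bool
    notes: tuple = field(default_factory=tuple)


def _wilcoxon_exact_p(doubled_ranks: np.ndarray, s: int) -> float:
    """Two-sided exact signed-rank p via DP over the doubled-rank sum.

    ``doubled_ranks`` are 2x the midranks (integers even with ties);
    enumerates the null distribution of the positive-rank sum in
    O(n * total) and returns min(1, 2 * min tail) at observed sum ``s``.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    counts /= counts.sum()
    p_le = counts[: s + 1].sum()
    p_ge = counts[s:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _wilcoxon(d: np.ndarray, exact_max_n: int = 25):
    """Signed-rank test on differences; returns (W+, p, n_used, n_zeros, mode)."""
    d = np.asarray(d, dtype=float)
    n_zeros = int(np.sum(d == 0))
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, 0, n_zeros, "degenerate"
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        doubled = np.round(2 * ranks).astype(int)
        s = int(round(2 * w_pos))
        p = _wilcoxon_exact_p(doubled, s)
        return w_pos, p, n, n_zeros, "exact"
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    diff = w_pos - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if var > 0 else 0.0
    p = float(2.0 * sps.norm.sf(abs(z)))
    return w_pos, min(p, 1.0), n, n_zeros, "normal-approx"


def paired_compare(sample: PairedSample, method: str = "auto") -> ComparisonResult:
    """Paired pre/post test for one metric.

    ``auto`` selects the paired t-test for continuous metrics and the
    Wilcoxon signed-rank test for ordinal scores, matching standard usage
    for this study design (no per-metric normality testing).
    """
    if method == "auto":
        ordinal = sample.kind == "ordinal" or sample.metric.endswith(ORDINAL_SUFFIX)
        method = "wilcoxon" if ordinal else "t"
    if method not in ("t", "wilcoxon"):
        raise InvalidInputError(f"unknown method {method!r}")
    a, b = sample.values_aa1, sample.values_aa2
    notes = ["no multiple-testing correction applied"]
    d = b - a
    if method == "t":
        if sample.n < 2:
            raise InvalidInputError("paired t-test needs >= 2 pairs")
        if np.all(d == 0):
            stat, p = 0.0, 1.0
            notes.append("degenerate: all paired differences are zero")
        else:
            stat, p = sps.ttest_rel(b, a)
        kind = "parametric"
        test = "paired t-test"
    else:
        stat, p, n_used, n_zeros, mode = _wilcoxon(d)
        if mode == "degenerate":
            notes.append("degenerate: all paired differences are zero")
        else:
            notes.append(f"wilcoxon mode={mode}, zero differences dropped: {n_zeros}")
        kind = "nonparametric"
        test = "Wilcoxon signed-rank"
    return ComparisonResult(
        metric=sample.metric,
        units=sample.units,
        n=sample.n,
        summary_aa1=summarize(a, kind),
        summary_aa2=summarize(b, kind),
        test=test,
        statistic=float(stat),
        p_value=float(p),
        significant=bool(p < ALPHA),
        notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# table-level interface


def make_paired_sample(
    table: pd.DataFrame, metric: str, group: str | None = None
) -> PairedSample:
    """Build a PairedSample from a long metric table.

    ``table`` has columns participant_id, group, assessment (AA1/AA2) and
    metric columns; rows are filtered to ``group`` when given.
    """
    t = table if group is None else table[table["group"] == group]
    if metric not in t.columns:
        raise InvalidInputError(f"metric column {metric!r} not in table")
    wide = t.pivot(index="participant_id", columns="assessment", values=metric)
    if "AA1" not in wide.columns or "AA2" not in wide.columns:
        raise AlignmentError("table must contain both AA1 and AA2 assessments")
    if wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist()
        raise AlignmentError(f"missing pair for participants: {missing}")
    groups = None
    if "group" in t.columns:
        groups = tuple(t.drop_duplicates("participant_id").set_index("participant_id").loc[wide.index, "group"])
    units = metric.rsplit("_", 1)[-1]
    return PairedSample(
        ids=tuple(wide.index),
        values_aa1=wide["AA1"].to_numpy(),
        values_aa2=wide["AA2"].to_numpy(),
        metric=metric,
        units=units,
        groups=groups,
        kind="ordinal" if metric.endswith(ORDINAL_SUFFIX) else "continuous",
    )


def stratified_compare(
    table: pd.DataFrame, metric: str, method: str = "auto"
) -> dict[str, ComparisonResult]:
    """Independent paired comparison per participant group (no pooling)."""
    out: dict[str, ComparisonResult] = {}
    for g in sorted(table["group"].unique()):
        sub = table[table["group"] == g]
        n_pairs = sub["participant_id"].nunique()
        if n_pairs < 2:
            warnings.warn(f"stratum {g!r} has < 2 pairs; skipped", stacklevel=2)
            continue
        out[g] = paired_compare(make_paired_sample(sub, metric), method)
    return out


def compare_table(table: pd.DataFrame, metrics: Sequence[str] | None = None) -> pd.DataFrame:
    """Comparison of every metric across AA1/AA2, one row per metric."""
    from .metrics import METRIC_COLUMNS

    metrics = list(metrics) if metrics is not None else [m for m in METRIC_COLUMNS if m in table.columns]
    rows = []
    for m in metrics:
        res = paired_compare(make_paired_sample(table, m))
        rows.append(
            {
                "metric": m,
                "n": res.n,
                "AA1": str(res.summary_aa1),
                "AA2": str(res.summary_aa2),
                "test": res.test,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)


def likert_summary(feedback: pd.DataFrame) -> pd.DataFrame:
    """Per-item median [IQR] of 1-10 Likert responses.

    ``feedback`` is items × respondents (index = item text). Returns a frame
    with median, q1, q3 and a formatted ``median [q1–q3]`` column.
    """
    vals = feedback.to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals < 1) or np.any(vals > 10):
        raise InvalidInputError("Likert responses must be in [1, 10]")
    rows = []
    for item, row in feedback.iterrows():
        s = summarize(row.to_numpy(dtype=float), "nonparametric")
        rows.append(
            {"item": item, "median": s.center, "q1": s.spread[0], "q3": s.spread[1], "summary": str(s)}
        )
    return pd.DataFrame(rows).set_index("item")
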