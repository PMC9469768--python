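"""Tier binning, confusion matrices, classification metrics, and split machinery.

Free-chlorine predictions are discretized into regulatory tiers, either a
binary scheme (at the 0.5 mg/L threshold, with <=0.5 mg/L the positive class)
or a multiclass scheme (<=0.2, 0.2-0.5, >0.5 mg/L).  Confusion matrices are
stored with rows = predicted class and columns = true class.  All bin
boundaries are half-open on the left, i.e. a tier is ``(lo, hi]``; negative
regression predictions fall in the lowest bin, reflecting that a strip with no
visible color change is a genuine low-chlorine observation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

BINARY = "binary"
MULTICLASS = "multiclass"

SCHEME_LABELS: dict[str, tuple[str, ...]] = {
    BINARY: ("le_0.5", "gt_0.5"),
    MULTICLASS: ("le_0.2", "mid_0.2_0.5", "gt_0.5"),
}


class SchemeError(ValueError):
    """Raised for unknown schemes or scheme mismatches."""


def bin_concentration(c: float, scheme: str = MULTICLASS) -> str:
    """Map a concentration (mg/L, negatives allowed) to its tier label.

    Negative predictions land in the lowest bin.  Boundaries are half-open on
    the left: 0.2 is in ``le_0.2``, 0.5 is in ``mid_0.2_0.5`` (multiclass) and
    in ``le_0.5`` (binary).
    """
    if scheme not in SCHEME_LABELS:
        raise SchemeError(f"unknown scheme {scheme!r}")
    if math.isnan(c):
        raise ValueError("concentration is NaN")
    if scheme == BINARY:
        return "le_0.5" if c <= 0.5 else "gt_0.5"
    if c <= 0.2:
        return "le_0.2"
    if c <= 0.5:
        return "mid_0.2_0.5"
    return "gt_0.5"


@dataclass
class ConfusionMatrix:
    """K x K integer counts; ``counts[i, j]`` = predicted label i, true label j."""

    scheme: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        labels = SCHEME_LABELS.get(self.scheme)
        if labels is None:
            raise SchemeError(f"unknown scheme {self.scheme!r}")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected {k}x{k} counts for scheme {self.scheme!r}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def labels(self) -> tuple[str, ...]:
        return SCHEME_LABELS[self.scheme]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if other.scheme != self.scheme:
            raise SchemeError("cannot add confusion matrices of different schemes")
        return ConfusionMatrix(self.scheme, self.counts + other.counts)

    def to_frame(self) -> pd.DataFrame:
        """Printable layout: predicted class down the rows, true class across."""
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def confusion(true_tiers: Sequence[str], pred_tiers: Sequence[str], scheme: str) -> ConfusionMatrix:
    """Tally a confusion matrix (rows predicted, columns true)."""
    labels = SCHEME_LABELS.get(scheme)
    if labels is None:
        raise SchemeError(f"unknown scheme {scheme!r}")
    if len(true_tiers) != len(pred_tiers):
        raise ValueError("label sequences differ in length")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(true_tiers, pred_tiers):
        try:
            counts[index[p], index[t]] += 1
        except KeyError as exc:
            raise SchemeError(f"label {exc.args[0]!r} not valid for scheme {scheme!r}") from None
    return ConfusionMatrix(scheme, counts)


@dataclass
class MetricsReport:
    scheme: str
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    weighted_f1: float
    micro_f1: float
    undefined_classes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "support": self.support,
            "weighted_f1": self.weighted_f1,
            "micro_f1": self.micro_f1,
            "undefined_classes": self.undefined_classes,
        }


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class precision/recall/F1, support-weighted F1, micro F1.

    Per-class precision is TP over the predicted-row total, recall is TP over
    the true-column total.  Classes with a zero denominator are reported as 0
    and listed in ``undefined_classes`` (a warning is emitted).  Weighted F1
    weights each class's F1 by its true-class support.  Micro F1 pools TP/FP/FN
    over classes; for single-label classification it equals accuracy.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix: metrics undefined")
    counts = cm.counts
    labels = cm.labels
    tp = np.diag(counts).astype(float)
    pred_totals = counts.sum(axis=1).astype(float)  # row sums: all predicted as class i
    true_totals = counts.sum(axis=0).astype(float)  # column sums: all truly class j

    precision, recall, f1 = {}, {}, {}
    undefined: list[str] = []
    for i, lab in enumerate(labels):
        pr, bad_pr = _safe_div(tp[i], pred_totals[i])
        re, bad_re = _safe_div(tp[i], true_totals[i])
        fv, bad_f = _safe_div(2 * pr * re, pr + re)
        precision[lab], recall[lab], f1[lab] = pr, re, fv
        if bad_pr or bad_re or bad_f:
            undefined.append(lab)
    if undefined:
        warnings.warn(
            f"zero-denominator metrics treated as 0 for classes {undefined}",
            RuntimeWarning,
            stacklevel=2,
        )

    accuracy = float(tp.sum() / total)
    support = {lab: int(true_totals[i]) for i, lab in enumerate(labels)}
    weighted_f1 = float(sum(f1[lab] * support[lab] for lab in labels) / total)
    # pooled counts: micro precision == micro recall == accuracy here
    micro_tp = tp.sum()
    micro_fp = (pred_totals - tp).sum()
    micro_fn = (true_totals - tp).sum()
    micro_pr = micro_tp / (micro_tp + micro_fp)
    micro_re = micro_tp / (micro_tp + micro_fn)
    micro_f1 = float(2 * micro_pr * micro_re / (micro_pr + micro_re)) if micro_pr + micro_re else 0.0

    return MetricsReport(
        scheme=cm.scheme,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        weighted_f1=weighted_f1,
        micro_f1=micro_f1,
        undefined_classes=undefined,
    )


def percent(x: float) -> int:
    """Round a [0, 1] metric to a whole percent, half away from zero."""
    return int(math.floor(100.0 * x + 0.5))


def stratified_split(
    rows: pd.DataFrame,
    train_fraction: float,
    seed: int,
    group_col: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split preserving per-group proportions (largest-remainder apportionment).

    The total training size is ``round(n * train_fraction)``; per-group counts
    are the floors of ``n_g * train_fraction`` topped up in order of largest
    fractional remainder.  Selection within a group is uniform given ``seed``.
    """
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must be in (0, 1]")
    if rows.empty:
        raise ValueError("no rows to split")
    rng = np.random.default_rng(seed)
    sizes = rows.groupby(group_col, sort=True).size()
    if (sizes == 0).any():
        raise ValueError("empty group")
    target_total = int(round(len(rows) * train_fraction))
    quotas = sizes * train_fraction
    base = np.floor(quotas).astype(int)
    remainders = quotas - base
    deficit = target_total - int(base.sum())
    order = np.argsort(-remainders.to_numpy(), kind="stable")
    take = base.copy()
    for idx in order[:max(deficit, 0)]:
        take.iloc[idx] += 1
    train_idx: list = []
    for g, n_take in take.items():
        members = rows.index[rows[group_col] == g].to_numpy()
        chosen = rng.choice(members, size=min(int(n_take), len(members)), replace=False)
        train_idx.extend(chosen.tolist())
    train_mask = rows.index.isin(train_idx)
    train, test = rows[train_mask], rows[~train_mask]
    if test.empty:
        warnings.warn("test set is empty (train_fraction too high)", RuntimeWarning, stacklevel=2)
    return train, test


def resampled_validation(
    rows: pd.DataFrame,
    fit_predict: Callable[[pd.DataFrame, pd.DataFrame], Sequence[float]],
    n_repeats: int = 10,
    train_fraction: float = 0.67,
    seed: int = 0,
    scheme: str = BINARY,
    conc_col: str = "concentration",
) -> tuple[list[MetricsReport | None], pd.DataFrame]:
    """Repeated stratified splits: fit on train, score tiers on test.

    ``fit_predict(train, test)`` returns predicted concentrations for the test
    rows.  Per-repeat fit errors are recorded (``None`` report) and the loop
    continues.  Returns the per-repeat reports and a summary frame with the
    mean and standard deviation of accuracy and weighted F1.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    reports: list[MetricsReport | None] = []
    accs, wf1s = [], []
    for rep in range(n_repeats):
        train, test = stratified_split(rows, train_fraction, seed=seed + rep)
        try:
            preds = fit_predict(train, test)
        except Exception as exc:  # keep resampling going; surface per-repeat failures
            warnings.warn(f"repeat {rep} failed: {exc}", RuntimeWarning, stacklevel=2)
            reports.append(None)
            continue
        true_tiers = [bin_concentration(c, scheme) for c in test[conc_col]]
        pred_tiers = [bin_concentration(c, scheme) for c in preds]
        rep_metrics = metrics(confusion(true_tiers, pred_tiers, scheme))
        reports.append(rep_metrics)
        accs.append(rep_metrics.accuracy)
        wf1s.append(rep_metrics.weighted_f1)
    summary = pd.DataFrame(
        {
            "metric": ["accuracy", "weighted_f1"],
            "mean": [float(np.mean(accs)) if accs else np.nan, float(np.mean(wf1s)) if wf1s else np.nan],
            "sd": [float(np.std(accs, ddof=0)) if accs else np.nan, float(np.std(wf1s, ddof=0)) if wf1s else np.nan],
            "n_ok": [len(accs), len(wf1s)],
        }
    )
    return reports, summary


def proportion_z_test(successes1: int, n1: int, successes2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z test, two-sided.

    z = (p1 - p2) / sqrt(p (1 - p) (1/n1 + 1/n2)) with p the pooled proportion.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= successes1 <= n1 and 0 <= successes2 <= n2):
        raise ValueError("successes out of range")
    pooled = (successes1 + successes2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        if successes1 / n1 == successes2 / n2:
            return 0.0, 1.0
        raise ValueError("zero pooled variance")
    z, p = proportions_ztest([successes1, successes2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


def multi_group_proportion_tests(successes: Sequence[int], ns: Sequence[int]) -> dict:
    """All pairwise pooled z tests plus an overall chi-square for >2 groups.

    A single pairwise z statistic is not defined across three groups, so each
    pair is tested separately and a 2xK chi-square tests overall homogeneity.
    """
    if len(successes) != len(ns) or len(successes) < 2:
        raise ValueError("need matching successes/ns for at least two groups")
    pairwise = {}
    for i in range(len(ns)):
        for j in range(i + 1, len(ns)):
            z, p = proportion_z_test(successes[i], ns[i], successes[j], ns[j])
            pairwise[(i, j)] = {"z": z, "p": p}
    table = np.array([list(successes), [n - s for s, n in zip(successes, ns)]])
    chi2, chi_p, dof, _ = sps.chi2_contingency(table)
    return {"pairwise": pairwise, "chi2": float(chi2), "chi2_p": float(chi_p), "dof": int(dof)}
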