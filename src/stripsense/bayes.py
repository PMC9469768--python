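"""Conditional-probability analysis of repeated tier measurements.

Given an observed confusion matrix, this module turns its counts into
empirical classification likelihoods P(predicted | true) and applies Bayes'
rule to ask how surprising a new reading is given earlier readings at the
same location — e.g. the chance that today's sample reads <=0.5 mg/L when the
two previous samples both read >0.5 mg/L.  A low probability flags the new
reading as a likely misclassification worth re-checking with a reference
instrument.

The sequence-of-samples computation uses one explicit model: all samples at
the location share a single unknown true tier, the prior over that tier is
the empirical true-class marginal of the confusion matrix, and individual
classifications are conditionally independent given the true tier with
likelihoods taken from the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .classify import ConfusionMatrix


@dataclass(frozen=True)
class BayesInputs:
    """Ingredients of a binary Bayes update.

    prior: P(A); likelihood: P(B | A); complement_likelihood: P(B | not A).
    """

    prior: float
    likelihood: float
    complement_likelihood: float

    def __post_init__(self) -> None:
        for name in ("prior", "likelihood", "complement_likelihood"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def bayes_posterior(inputs: BayesInputs) -> float:
    """P(A | B) = P(B|A) P(A) / [P(B|A) P(A) + P(B|-A) (1 - P(A))]."""
    num = inputs.likelihood * inputs.prior
    marginal = num + inputs.complement_likelihood * (1.0 - inputs.prior)
    if marginal == 0.0:
        raise ZeroDivisionError("marginal P(B) is zero; posterior undefined")
    return num / marginal


def _column_likelihoods(cm: ConfusionMatrix, orientation: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (L, marginal): L[p, t] = P(predicted=p | true=t), marginal over true.

    ``orientation='rows_predicted'`` reads the matrix as stored (rows =
    predicted, columns = true); ``'rows_true'`` treats the stored rows as true
    classes instead, i.e. operates on the transpose.  Both are offered because
    printed confusion tables in the field are not consistent about it.
    """
    if orientation == "rows_predicted":
        counts = cm.counts.astype(float)
    elif orientation == "rows_true":
        counts = cm.counts.T.astype(float)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    true_totals = counts.sum(axis=0)
    if (true_totals == 0).any():
        raise ValueError("a true class has zero observations; likelihoods undefined")
    likelihoods = counts / true_totals
    marginal = true_totals / true_totals.sum()
    return likelihoods, marginal


def empirical_likelihood(
    cm: ConfusionMatrix,
    true_class: str,
    predicted_set: Iterable[str],
    orientation: str = "rows_predicted",
) -> float:
    """Empirical P(predicted in set | true class) from confusion counts."""
    labels = list(cm.labels)
    t = labels.index(true_class)
    pred_idx = [labels.index(p) for p in predicted_set]
    likelihoods, _ = _column_likelihoods(cm, orientation)
    return float(likelihoods[pred_idx, t].sum())


@dataclass
class CaseReport:
    label: str
    probability: float
    n_prior: int
    prior_predicted_class: str
    present_predicted_set: tuple[str, ...]
    assumption: str
    orientation: str


def sequence_case_probability(
    cm: ConfusionMatrix,
    prior_predicted_class: str,
    n_prior: int,
    present_predicted_set: Sequence[str],
    assumption: str = "shared_true_class",
    orientation: str = "rows_predicted",
    label: str = "",
) -> CaseReport:
    """P(present reading in set | n_prior earlier readings all gave one class).

    Under the shared-true-class model the answer is a posterior-weighted
    average: condition the empirical tier prior on the earlier readings, then
    propagate through the per-tier likelihood of the present reading::

        P = sum_t  w_t * P(present in S | true=t),
        w_t ∝ P(true=t) * P(prior class | true=t) ** n_prior

    With ``n_prior=0`` this reduces to the marginal probability of the
    present reading.
    """
    if assumption != "shared_true_class":
        raise ValueError(f"unsupported assumption {assumption!r}")
    if n_prior < 0:
        raise ValueError("n_prior must be >= 0")
    labels = list(cm.labels)
    p_idx = labels.index(prior_predicted_class)
    s_idx = [labels.index(s) for s in present_predicted_set]
    likelihoods, marginal = _column_likelihoods(cm, orientation)
    weights = marginal * likelihoods[p_idx, :] ** n_prior
    norm = weights.sum()
    if norm == 0.0:
        raise ZeroDivisionError("conditioning event has zero empirical probability")
    weights = weights / norm
    prob = float(weights @ likelihoods[s_idx, :].sum(axis=0))
    return CaseReport(
        label=label,
        probability=prob,
        n_prior=n_prior,
        prior_predicted_class=prior_predicted_class,
        present_predicted_set=tuple(present_predicted_set),
        assumption=assumption,
        orientation=orientation,
    )
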