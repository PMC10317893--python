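"""The published decision-tree risk calculator and evaluation metrics.

The published model stratifies patients by lymph-node stage and
postoperative thyroglobulin: node-positive patients with Tg > 23.3 ng/mL
carry an 83% probability of a positive post-treatment scan; node-negative
patients are split at 35 and 7.1 ng/mL into 56.3%, 15.2% and 5.8% risk
bands.  The node-positive low-Tg terminal risk was not reported; it is
surfaced as "not available" (risk ``None``) with predicted class
negative rather than silently imputed.

Classification uses the standard majority-of-node rule: predicted
positive iff terminal risk > 0.5, which makes exactly the 83% and 56.3%
terminals positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .ctree import FitParams, FittedTree, Predictor, Split, Terminal

__all__ = [
    "PUBLISHED_CUTOFFS", "PUBLISHED_RISKS", "published_model", "predict_risk",
    "MetricsBundle", "confusion_metrics", "auc", "evaluate",
]

PUBLISHED_CUTOFFS = {"n1_tg": 23.3, "n0_tg_hi": 35.0, "n0_tg_lo": 7.1}
PUBLISHED_RISKS = {"n1_hi": 0.83, "n0_hi": 0.563, "n0_mid": 0.152, "n0_lo": 0.058}


def published_model() -> FittedTree:
    """The published tree as an executable :class:`FittedTree` constant.

    Node ids follow the preorder numbering of the published tree (the
    node-negative subtree first), so the three inner Tg nodes carry ids
    2, 3 and 7.  Terminal weights are unknown and stored as ``None``.
    """
    t_lo = Terminal(4, None, PUBLISHED_RISKS["n0_lo"])
    t_mid = Terminal(5, None, PUBLISHED_RISKS["n0_mid"])
    t_hi = Terminal(6, None, PUBLISHED_RISKS["n0_hi"])
    t_n1_lo = Terminal(8, None, None, klass=0)      # risk not reported
    t_n1_hi = Terminal(9, None, PUBLISHED_RISKS["n1_hi"])
    nan = float("nan")
    n0 = Split(2, "tg", PUBLISHED_CUTOFFS["n0_tg_hi"], None, nan, nan,
               Split(3, "tg", PUBLISHED_CUTOFFS["n0_tg_lo"], None, nan, nan,
                     t_lo, t_mid),
               t_hi)
    n1 = Split(7, "tg", PUBLISHED_CUTOFFS["n1_tg"], None, nan, nan,
               t_n1_lo, t_n1_hi)
    root = Split(1, "n_stage", 0.0, None, nan, nan, n0, n1)
    predictors = [Predictor("tg", "continuous"), Predictor("n_stage", "ordinal", (0, 1))]
    return FittedTree(root, FitParams(), predictors,
                      provenance={"model": "published"})


def predict_risk(model: FittedTree, data) -> Union[tuple, pd.DataFrame]:
    """Predict terminal id, risk and class for one record or a whole table.

    Single records (mapping / PatientRecord) return a
    ``(terminal_id, risk, klass)`` tuple; cohorts and data frames return
    the prediction frame from :meth:`FittedTree.predict`.
    """
    import dataclasses

    if isinstance(data, (Cohort, pd.DataFrame)):
        return model.predict(data)
    if dataclasses.is_dataclass(data):
        data = dataclasses.asdict(data)
    out = model.predict(pd.DataFrame([dict(data)])).iloc[0]
    risk = None if np.isnan(out["risk"]) else float(out["risk"])
    return int(out["node_id"]), risk, int(out["klass"])


@dataclass
class MetricsBundle:
    """Confusion counts and the derived diagnostic proportions.

    Ratios with a zero denominator are ``None`` (absent), mirroring how
    per-center tables leave undefined cells blank.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    auc: Optional[float] = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def _ratio(num: int, den: int) -> Optional[float]:
        return None if den == 0 else num / den

    @property
    def accuracy(self) -> Optional[float]:
        return self._ratio(self.tp + self.tn, self.n)

    @property
    def ppv(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def sensitivity(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def prevalence(self) -> Optional[float]:
        return self._ratio(self.tp + self.fn, self.n)

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "accuracy": self.accuracy, "ppv": self.ppv, "npv": self.npv,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "prevalence": self.prevalence, "auc": self.auc}


def confusion_metrics(predicted, truth) -> MetricsBundle:
    """Confusion counts and ratios for binary predictions against truth."""
    predicted = np.asarray(predicted, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if predicted.size == 0:
        raise ValueError("empty input")
    tp = int(((predicted == 1) & (truth == 1)).sum())
    fp = int(((predicted == 1) & (truth == 0)).sum())
    tn = int(((predicted == 0) & (truth == 0)).sum())
    fn = int(((predicted == 0) & (truth == 1)).sum())
    return MetricsBundle(tp, fp, tn, fn)


def auc(scores, truth) -> Optional[float]:
    """Rank-based (concordance) AUC with midrank tie handling.

    Equals the probability that a random positive outranks a random
    negative, counting ties as one half.  ``None`` when only one class
    is present.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=np.int64)
    n1 = int(truth.sum())
    n0 = truth.size - n1
    if n1 == 0 or n0 == 0:
        return None
    ranks = stats.rankdata(scores)
    u = ranks[truth == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def evaluate(model: FittedTree, cohort: Cohort,
             na_risk_score: Optional[float] = None) -> MetricsBundle:
    """Apply a model to a cohort and bundle all metrics including AUC.

    ``na_risk_score`` is the ranking score used for risk-unavailable
    terminals when computing AUC (classification is unaffected); when
    the model has no such terminal it is ignored.
    """
    pred = model.predict(cohort)
    truth = cohort.endpoint
    bundle = confusion_metrics(pred["klass"].to_numpy(), truth)
    scores = pred["risk"].to_numpy(dtype=float)
    if np.isnan(scores).any():
        if na_risk_score is None:
            from .simulate import calibrate_baseline_risk, default_config
            na_risk_score = calibrate_baseline_risk(default_config())
        scores = np.where(np.isnan(scores), na_risk_score, scores)
    bundle.auc = auc(scores, truth)
    return bundle
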