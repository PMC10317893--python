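"""Stability-based variable selection and repeated stratified cross-validation.

The two-stage internal validation procedure:

1. *Stability selection* — refit the tree on class-stratified bootstrap
   resamples (dataset varied at constant size and event proportion) and
   record, for every candidate predictor, the fraction of iterations in
   which it appears in at least one inner node.  Predictors selected in
   at least 95% of iterations are retained.
2. *Monte Carlo cross-validation* — repeated stratified random 70:30
   train/validation splits; per repeat the tree is refitted on the
   training part, diagnostic metrics are computed on both parts, and the
   node cutoffs are read off trees whose topology matches the published
   shape (root on N stage, Tg splits beneath).  Cutoffs and metrics are
   aggregated as median (IQR); structurally discordant repeats are
   excluded from cutoff aggregation and counted, never force-matched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import calculator
from .cohort import Cohort
from .ctree import FitParams, FittedTree, Predictor, default_predictors, grow_tree

__all__ = [
    "CANONICAL_KEYS", "StabilityResult", "RepeatResult", "CVReport",
    "stratified_resample", "stability_selection", "mc_cross_validate",
    "extract_canonical_cutoffs", "evaluate_by_center",
]

#: Canonical node keys of the published topology.
CANONICAL_KEYS = ("n1_tg", "n0_tg_hi", "n0_tg_lo")


def _class_indices(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both endpoint classes must be present")
    return pos, neg


def _stratified_bootstrap_indices(y: np.ndarray, rng: np.random.Generator,
                                  fraction: float = 1.0,
                                  replace: bool = True) -> np.ndarray:
    """Within-class resample preserving each class count (to nearest int)."""
    pos, neg = _class_indices(y)
    parts = []
    for cls in (pos, neg):
        m = int(round(fraction * cls.size))
        if m < 1:
            raise ValueError("resample fraction leaves an empty class")
        parts.append(rng.choice(cls, size=m, replace=replace))
    idx = np.concatenate(parts)
    rng.shuffle(idx)
    return idx


def stratified_resample(cohort: Cohort, seed, *, fraction: float = 1.0,
                        replace: bool = True) -> Cohort:
    """Class-stratified resample of a cohort, order shuffled by ``seed``.

    With the defaults this is a stratified bootstrap: sampling with
    replacement within each endpoint class, preserving both class counts
    exactly.  ``replace=False`` with ``fraction < 1`` gives the
    subsampling variant.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = _stratified_bootstrap_indices(cohort.endpoint, rng, fraction, replace)
    out = cohort.subset(idx, provenance=f"{cohort.provenance}|resample")
    return out


@dataclass
class StabilityResult:
    """Per-variable selection frequencies over resampled refits."""

    iterations: int
    frequencies: dict[str, float]
    threshold: float
    skipped: int = 0

    @property
    def retained(self) -> tuple[str, ...]:
        return tuple(name for name, f in self.frequencies.items()
                     if f >= self.threshold)

    def to_dict(self) -> dict:
        return {"iterations": self.iterations, "threshold": self.threshold,
                "skipped": self.skipped, "frequencies": self.frequencies,
                "retained": list(self.retained)}


def stability_selection(cohort: Cohort,
                        predictors: Optional[Sequence[Predictor]] = None,
                        iterations: int = 1000,
                        freq_threshold: float = 0.95,
                        params: FitParams = FitParams(),
                        seed: Optional[int] = None,
                        fraction: float = 1.0,
                        replace: bool = True) -> StabilityResult:
    """Bootstrap selection frequencies for every candidate predictor.

    A predictor counts as selected in an iteration when it appears in at
    least one inner node of that iteration's tree.  Iterations whose fit
    fails are skipped and counted.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    preds = list(predictors) if predictors is not None else default_predictors()
    y = cohort.endpoint
    rng = np.random.default_rng(seed)
    counts = {p.name: 0 for p in preds}
    skipped = 0
    for _ in range(iterations):
        idx = _stratified_bootstrap_indices(y, rng, fraction, replace)
        try:
            tree = grow_tree(cohort.df.iloc[idx].reset_index(drop=True),
                             preds, params, y=y[idx])
        except ValueError:
            skipped += 1
            continue
        for name in tree.inner_predictor_names():
            counts[name] += 1
    done = iterations - skipped
    if done == 0:
        raise RuntimeError("every stability iteration failed")
    freqs = {name: counts[name] / done for name in counts}
    return StabilityResult(done, freqs, freq_threshold, skipped)


def extract_canonical_cutoffs(tree: FittedTree) -> Optional[dict[str, float]]:
    """Read the three Tg cutoffs off a tree with the published topology.

    Canonical shape: root splits on ``n_stage``; the node-positive
    subtree opens with a Tg split (its cutoff is ``n1_tg``); the
    node-negative subtree opens with a Tg split exactly one of whose
    children splits on Tg again — the larger of the two cutoffs is
    ``n0_tg_hi``, the smaller ``n0_tg_lo``.  Any other shape returns
    ``None`` (structural mismatch — data, not an error).
    """
    root = tree.root
    if root.is_terminal or root.predictor != "n_stage":
        return None
    n0, n1 = root.left, root.right            # n_stage <= 0 goes left
    if n1.is_terminal or n1.predictor != "tg":
        return None
    if n0.is_terminal or n0.predictor != "tg":
        return None
    child_cuts = [c.cutpoint for c in (n0.left, n0.right)
                  if not c.is_terminal and c.predictor == "tg"]
    if len(child_cuts) != 1:
        return None
    c1, c2 = float(n0.cutpoint), float(child_cuts[0])
    return {"n1_tg": float(n1.cutpoint),
            "n0_tg_hi": max(c1, c2), "n0_tg_lo": min(c1, c2)}


@dataclass
class RepeatResult:
    train_metrics: calculator.MetricsBundle
    val_metrics: calculator.MetricsBundle
    cutoffs: Optional[dict[str, float]]
    tree: Optional[FittedTree] = None


_METRICS = ("accuracy", "ppv", "npv", "sensitivity", "specificity", "auc")


@dataclass
class CVReport:
    """Per-repeat metrics and cutoffs with median/IQR aggregates."""

    repeats: int
    train_fraction: float
    results: list[RepeatResult] = field(default_factory=list)

    @property
    def n_concordant(self) -> int:
        return sum(r.cutoffs is not None for r in self.results)

    @staticmethod
    def _median_iqr(values: list) -> Optional[dict]:
        vals = [v for v in values if v is not None and np.isfinite(v)]
        if not vals:
            return None
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return {"median": float(med), "q1": float(q1), "q3": float(q3),
                "n": len(vals)}

    def metric_summary(self, part: str, metric: str) -> Optional[dict]:
        attr = "train_metrics" if part == "train" else "val_metrics"
        if metric == "auc":
            values = [getattr(r, attr).auc for r in self.results]
        else:
            values = [getattr(getattr(r, attr), metric) for r in self.results]
        return self._median_iqr(values)

    def cutoff_summary(self, key: str) -> Optional[dict]:
        values = [r.cutoffs[key] for r in self.results if r.cutoffs is not None]
        return self._median_iqr(values)

    def to_dict(self) -> dict:
        return {
            "repeats": self.repeats,
            "train_fraction": self.train_fraction,
            "n_concordant": self.n_concordant,
            "metrics": {part: {m: self.metric_summary(part, m) for m in _METRICS}
                        for part in ("train", "validation")},
            "cutoffs": {k: self.cutoff_summary(k) for k in CANONICAL_KEYS},
            "per_repeat": [
                {"train": r.train_metrics.to_dict(), "validation": r.val_metrics.to_dict(),
                 "cutoffs": r.cutoffs} for r in self.results],
        }

    def to_json(self, path=None, **kw) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _stratified_split(y: np.ndarray, rng: np.random.Generator,
                      train_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation split preserving class counts."""
    train, val = [], []
    for cls in _class_indices(y):
        perm = rng.permutation(cls)
        m = int(round(train_fraction * cls.size))
        if m < 1 or m >= cls.size:
            raise ValueError("degenerate split: a class is empty in one part")
        train.append(perm[:m])
        val.append(perm[m:])
    return np.concatenate(train), np.concatenate(val)


def mc_cross_validate(cohort: Cohort,
                      predictors: Optional[Sequence[Predictor]] = None,
                      repeats: int = 200,
                      train_fraction: float = 0.70,
                      params: FitParams = FitParams(),
                      seed: Optional[int] = None,
                      store_trees: bool = False) -> CVReport:
    """Monte Carlo cross-validation with node-threshold aggregation.

    Each repeat draws an independent stratified ``train_fraction`` split,
    fits the tree on the training part, evaluates the classification
    rule (terminal risk > 0.5) on both parts, and extracts the canonical
    cutoffs where the fitted topology matches the published shape.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    preds = list(predictors) if predictors is not None else default_predictors()
    y = cohort.endpoint
    rng = np.random.default_rng(seed)
    report = CVReport(repeats, train_fraction)
    for _ in range(repeats):
        tr, va = _stratified_split(y, rng, train_fraction)
        assert np.intersect1d(tr, va).size == 0
        assert tr.size + va.size == y.size
        tree = grow_tree(cohort.df.iloc[tr].reset_index(drop=True), preds,
                         params, y=y[tr])
        result = RepeatResult(
            train_metrics=calculator.evaluate(tree, cohort.subset(tr)),
            val_metrics=calculator.evaluate(tree, cohort.subset(va)),
            cutoffs=extract_canonical_cutoffs(tree),
            tree=tree if store_trees else None,
        )
        report.results.append(result)
    return report


def evaluate_by_center(model: FittedTree, cohort: Cohort,
                       na_risk_score: Optional[float] = None) -> pd.DataFrame:
    """Apply a fixed model per center and pooled; one metrics row each.

    Centers with a single outcome class report an absent (NaN) AUC.
    """
    labels = cohort.df["center"]
    centers = [c for c in pd.unique(labels) if c is not None and not pd.isna(c)]
    rows = {}

    def metrics_row(sub: Cohort) -> dict:
        bundle = calculator.evaluate(model, sub, na_risk_score=na_risk_score)
        row = bundle.to_dict()
        row["n"] = bundle.n
        return row

    for center in centers:
        idx = np.flatnonzero((labels == center).to_numpy())
        rows[str(center)] = metrics_row(cohort.subset(idx))
    rows["pooled"] = metrics_row(cohort)
    out = pd.DataFrame.from_dict(rows, orient="index")
    cols = ["n", "prevalence", "accuracy", "ppv", "npv",
            "sensitivity", "specificity", "auc", "tp", "fp", "tn", "fn"]
    return out[cols]
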