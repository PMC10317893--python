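"""Conditional inference tree for a binary endpoint over mixed predictors.

Recursive binary partitioning in the permutation-test framework: at each
node the association between every candidate predictor and the endpoint
is scored by the standardized linear statistic

    T = sum_i w_i g(x_i) y_i

with conditional expectation and covariance computed under random
permutation of the endpoint.  The minimum p-value is Bonferroni-adjusted
over the number of candidates; growth stops when no predictor is
significant at ``alpha``, so stopping is significance-based and no
pruning is needed.  The split point of the selected predictor maximizes
the standardized two-sample statistic over admissible cutpoints
(``x <= cutpoint`` goes left).

Continuous and ordinal predictors enter through their scalar score
(asymptotically normal test); nominal predictors enter through the
level-indicator vector (quadratic-form test, chi-square on the rank of
the conditional covariance).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (ATA_LEVELS, HISTOLOGY_LEVELS, SEX_LEVELS, Cohort)

__all__ = [
    "Predictor", "FitParams", "AssociationResult", "Terminal", "Split",
    "FittedTree", "association_test", "find_cutpoint", "find_level_split",
    "select_split_variable", "grow_tree", "predict_node", "default_predictors",
]

#: Relative tolerance on singular values for the covariance pseudoinverse.
_PINV_RTOL = 1e-8


@dataclass(frozen=True)
class Predictor:
    """A candidate split variable and how it enters the test statistic.

    kind:
        ``continuous`` / ``ordinal`` — scalar influence (ordinal scores
        must respect the level order); ``nominal`` — k-level indicator.
    levels:
        Level vocabulary for ordinal/nominal predictors, in score order.
    """

    name: str
    kind: str
    levels: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal", "nominal"):
            raise ValueError(f"unknown predictor kind: {self.kind!r}")
        if self.kind == "nominal" and not self.levels:
            raise ValueError("nominal predictor needs levels")


def default_predictors() -> list[Predictor]:
    """The nine candidate predictors, in the canonical tie-break order."""
    return [
        Predictor("tg", "continuous"),
        Predictor("n_stage", "ordinal", (0, 1)),
        Predictor("sex", "nominal", SEX_LEVELS),
        Predictor("t_stage", "ordinal", (1, 2, 3, 4)),
        Predictor("histology", "nominal", HISTOLOGY_LEVELS),
        Predictor("ata_risk", "ordinal", ATA_LEVELS),
        Predictor("tsh", "continuous"),
        Predictor("age", "continuous"),
        Predictor("raiu", "continuous"),
    ]


@dataclass(frozen=True)
class FitParams:
    """Stopping and admissibility parameters for tree growth."""

    alpha: float = 0.05
    minsplit: int = 20
    minbucket: int = 7
    max_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.minbucket < 1:
            raise ValueError("minbucket must be >= 1")
        if self.minsplit < 2 * self.minbucket:
            raise ValueError("minsplit must be >= 2 * minbucket")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")


@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    p_value: float
    df: int


def _moments(y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    W = float(w.sum())
    ybar = float((w * y).sum() / W)
    V = float((w * (y - ybar) ** 2).sum() / W)
    return W, ybar, V


def association_test(x: np.ndarray, y: np.ndarray,
                     weights: Optional[np.ndarray] = None) -> AssociationResult:
    """Permutation-framework association test between x and a binary y.

    ``x`` is either a scalar score vector (n,) or an indicator matrix
    (n, k) for a nominal predictor.  Degenerate inputs (constant x or
    constant y) return p = 1 by convention and are never selected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if (w > 0).sum() < 2:
        raise ValueError("need at least 2 records with positive weight")

    W, ybar, V = _moments(y, w)
    if V <= 0 or W <= 1:
        return AssociationResult(0.0, 1.0, 0)

    g = x[:, None] if x.ndim == 1 else x
    T = g.T @ (w * y)                      # (k,)
    s = g.T @ w                            # (k,) = sum_i w_i g_i
    M2 = g.T @ (g * w[:, None])            # (k,k) = sum_i w_i g_i g_i'
    mu = s * ybar
    cov = (W / (W - 1.0)) * V * M2 - (1.0 / (W - 1.0)) * V * np.outer(s, s)
    c = T - mu

    if g.shape[1] == 1:
        var = float(cov[0, 0])
        if var <= 0:
            return AssociationResult(0.0, 1.0, 0)
        z = abs(float(c[0])) / math.sqrt(var)
        return AssociationResult(z, float(2.0 * stats.norm.sf(z)), 1)

    evals, evecs = np.linalg.eigh(cov)
    tol = _PINV_RTOL * max(float(evals[-1]), 0.0)
    keep = evals > tol
    rank = int(keep.sum())
    if rank == 0:
        return AssociationResult(0.0, 1.0, 0)
    proj = evecs[:, keep].T @ c
    stat = float(np.sum(proj ** 2 / evals[keep]))
    return AssociationResult(stat, float(stats.chi2.sf(stat, rank)), rank)


def _encode(df: pd.DataFrame, pred: Predictor) -> np.ndarray:
    """Raw column -> numeric scores (scalar kinds) or integer codes (nominal)."""
    col = df[pred.name]
    if pred.kind == "continuous":
        return col.to_numpy(dtype=float)
    levels = list(pred.levels)
    codes = np.asarray([levels.index(v) for v in col], dtype=np.int64)
    return codes.astype(float) if pred.kind == "ordinal" else codes


def _indicator(codes: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((codes.shape[0], k))
    out[np.arange(codes.shape[0]), codes.astype(np.int64)] = 1.0
    return out


def _two_sample_stats(WA: np.ndarray, TA: np.ndarray, W: float, ybar: float,
                      V: float) -> np.ndarray:
    """Standardized statistic for left-indicator influence, vectorized."""
    var = V * WA * (W - WA) / (W - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(TA - WA * ybar) / np.sqrt(var)
    z[~np.isfinite(z)] = -np.inf
    return z


def find_cutpoint(x: np.ndarray, y: np.ndarray,
                  weights: Optional[np.ndarray] = None,
                  params: FitParams = FitParams()) -> Optional[tuple[float, float]]:
    """Best cutpoint for a scalar predictor, or None if none is admissible.

    Scans every observed unique value ξ whose split ``x <= ξ`` leaves at
    least ``minbucket`` weight on each side and returns the ξ maximizing
    the standardized two-sample statistic; ties go to the smaller ξ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    order = np.argsort(x, kind="stable")
    xs, ys, ws = x[order], y[order], w[order]
    W, ybar, V = _moments(ys, ws)
    if V <= 0 or W <= 1:
        return None
    cw = np.cumsum(ws)
    cwy = np.cumsum(ws * ys)
    last = np.nonzero(np.diff(xs) != 0)[0]     # last index of each unique value bar the max
    if last.size == 0:
        return None
    WA, TA = cw[last], cwy[last]
    admissible = (WA >= params.minbucket) & (W - WA >= params.minbucket)
    if not admissible.any():
        return None
    z = _two_sample_stats(WA, TA, W, ybar, V)
    z[~admissible] = -np.inf
    # ties (within float tolerance) break toward the smaller cutpoint
    zmax = float(z.max())
    best = int(np.argmax(z >= zmax - 1e-9 * max(1.0, abs(zmax))))
    return float(xs[last[best]]), float(z[best])


def find_level_split(codes: np.ndarray, levels: Sequence, y: np.ndarray,
                     weights: Optional[np.ndarray] = None,
                     params: FitParams = FitParams()) -> Optional[tuple[tuple, float]]:
    """Best binary level-partition for a nominal predictor.

    Enumerates all 2^(k-1) - 1 proper binary partitions (represented by
    the subset containing the first level, which goes left) and returns
    the admissible subset maximizing the two-sample statistic.
    """
    codes = np.asarray(codes, dtype=np.int64)
    y = np.asarray(y, dtype=float)
    n = codes.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    W, ybar, V = _moments(y, w)
    if V <= 0 or W <= 1:
        return None
    k = len(levels)
    wl = np.bincount(codes, weights=w, minlength=k)
    wyl = np.bincount(codes, weights=w * y, minlength=k)
    best: Optional[tuple[tuple, float]] = None
    for mask in range(1, 2 ** k - 1):
        if not mask & 1:                      # canonical form: level 0 on the left
            continue
        members = [j for j in range(k) if mask >> j & 1]
        WA = float(wl[members].sum())
        if WA < params.minbucket or W - WA < params.minbucket:
            continue
        TA = np.array([wyl[members].sum()])
        z = float(_two_sample_stats(np.array([WA]), TA, W, ybar, V)[0])
        if best is None or z > best[1]:
            best = (tuple(levels[j] for j in members), z)
    return best


def select_split_variable(df: pd.DataFrame, y: np.ndarray,
                          predictors: Sequence[Predictor],
                          params: FitParams = FitParams(),
                          weights: Optional[np.ndarray] = None,
                          ) -> Optional[tuple[Predictor, float]]:
    """Bonferroni-adjusted variable selection at one node.

    Tests every candidate, adjusts the minimum p-value by the number of
    candidates, and returns the winning predictor if the adjusted p-value
    is <= alpha, else ``None`` (stop signal).  Ties on the p-value break
    toward the earlier predictor in the declared ordering.
    """
    if not predictors:
        raise ValueError("empty predictor list")
    best: Optional[tuple[Predictor, float]] = None
    for pred in predictors:
        enc = _encode(df, pred)
        x = _indicator(enc, len(pred.levels)) if pred.kind == "nominal" else enc
        res = association_test(x, y, weights)
        if best is None or res.p_value < best[1]:
            best = (pred, res.p_value)
    p_adj = min(1.0, len(predictors) * best[1])
    if p_adj > params.alpha:
        return None
    return best[0], p_adj


# --------------------------------------------------------------------------
# tree structure

@dataclass
class Terminal:
    """Leaf node: record weight, event fraction and predicted class."""

    node_id: int
    n: Optional[float]
    risk: Optional[float]
    klass: Optional[int] = None

    def __post_init__(self) -> None:
        if self.klass is None:
            if self.risk is None:
                raise ValueError("terminal needs a risk or an explicit class")
            self.klass = int(self.risk > 0.5)

    @property
    def is_terminal(self) -> bool:
        return True


@dataclass
class Split:
    """Inner node: ``x <= cutpoint`` (or ``level in level_subset``) goes left."""

    node_id: int
    predictor: str
    cutpoint: Optional[float]
    level_subset: Optional[tuple]
    p_adj: float
    statistic: float
    left: Union["Split", Terminal]
    right: Union["Split", Terminal]

    @property
    def is_terminal(self) -> bool:
        return False


TreeNode = Union[Split, Terminal]


@dataclass
class FittedTree:
    """A fitted binary recursive partition with per-node test results."""

    root: TreeNode
    params: FitParams
    predictors: list[Predictor]
    provenance: dict = field(default_factory=dict)

    # -- structure ---------------------------------------------------------
    def nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            out.append(node)
            if not node.is_terminal:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def terminals(self) -> list[Terminal]:
        return [n for n in self.nodes() if n.is_terminal]

    def inner_predictor_names(self) -> set[str]:
        return {n.predictor for n in self.nodes() if not n.is_terminal}

    @property
    def depth(self) -> int:
        def d(node: TreeNode) -> int:
            return 0 if node.is_terminal else 1 + max(d(node.left), d(node.right))

        return d(self.root)

    # -- prediction --------------------------------------------------------
    def _route_mask(self, node: Split, df: pd.DataFrame) -> np.ndarray:
        pred = next(p for p in self.predictors if p.name == node.predictor)
        col = df[node.predictor]
        if col.isna().any():
            raise ValueError(f"missing value for predictor {node.predictor!r}")
        if node.level_subset is not None:
            return col.isin(node.level_subset).to_numpy()
        if pred.kind == "ordinal" and pred.levels and not np.issubdtype(
                np.asarray(pred.levels).dtype, np.number):
            scores = np.asarray([list(pred.levels).index(v) for v in col], dtype=float)
        else:
            scores = col.to_numpy(dtype=float)
        return scores <= node.cutpoint

    def predict(self, data: Union[Cohort, pd.DataFrame]) -> pd.DataFrame:
        """Vectorized routing; returns node id, risk and predicted class per row."""
        df = data.df if isinstance(data, Cohort) else data
        n = len(df)
        node_id = np.zeros(n, dtype=np.int64)
        risk = np.full(n, np.nan)
        klass = np.zeros(n, dtype=np.int64)

        def walk(node: TreeNode, mask: np.ndarray) -> None:
            if not mask.any():
                return
            if node.is_terminal:
                node_id[mask] = node.node_id
                risk[mask] = np.nan if node.risk is None else node.risk
                klass[mask] = node.klass
                return
            left = np.zeros(n, dtype=bool)
            left[mask] = self._route_mask(node, df.loc[mask])
            walk(node.left, mask & left)
            walk(node.right, mask & ~left)

        walk(self.root, np.ones(n, dtype=bool))
        return pd.DataFrame({"node_id": node_id, "risk": risk, "klass": klass},
                            index=df.index)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(node: TreeNode) -> dict:
            if node.is_terminal:
                return {"id": node.node_id, "n": node.n, "risk": node.risk,
                        "class": node.klass}
            return {"id": node.node_id, "predictor": node.predictor,
                    "cutpoint": node.cutpoint,
                    "level_subset": list(node.level_subset) if node.level_subset else None,
                    "p_adj": node.p_adj, "statistic": node.statistic,
                    "children": [enc(node.left), enc(node.right)]}

        return {
            "params": {"alpha": self.params.alpha, "minsplit": self.params.minsplit,
                       "minbucket": self.params.minbucket,
                       "max_depth": self.params.max_depth},
            "predictors": [{"name": p.name, "kind": p.kind,
                            "levels": list(p.levels) if p.levels else None}
                           for p in self.predictors],
            "provenance": self.provenance,
            "root": enc(self.root),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FittedTree":
        def dec(node: dict) -> TreeNode:
            if "children" in node:
                left, right = (dec(c) for c in node["children"])
                subset = node.get("level_subset")
                return Split(node["id"], node["predictor"], node.get("cutpoint"),
                             tuple(subset) if subset else None,
                             node.get("p_adj", float("nan")),
                             node.get("statistic", float("nan")), left, right)
            return Terminal(node["id"], node.get("n"), node.get("risk"),
                            node.get("class"))

        params = FitParams(**doc["params"])
        preds = [Predictor(p["name"], p["kind"],
                           tuple(p["levels"]) if p["levels"] else None)
                 for p in doc["predictors"]]
        return cls(dec(doc["root"]), params, preds, doc.get("provenance", {}))

    def to_json(self, path=None, **kw) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "FittedTree":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))

    def render(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, prefix: str, label: str) -> None:
            if node.is_terminal:
                risk = "n/a" if node.risk is None else f"{node.risk:.3f}"
                lines.append(f"{prefix}{label}[{node.node_id}] n={node.n} risk={risk}")
                return
            if node.level_subset is not None:
                cond = f"{node.predictor} in {set(node.level_subset)}"
            else:
                cond = f"{node.predictor} <= {node.cutpoint:g}"
            lines.append(f"{prefix}{label}[{node.node_id}] {cond} (p_adj={node.p_adj:.2e})")
            walk(node.left, prefix + "  ", "yes: ")
            walk(node.right, prefix + "  ", "no:  ")

        walk(self.root, "", "")
        return "\n".join(lines)


def grow_tree(data: Union[Cohort, pd.DataFrame],
              predictors: Optional[Sequence[Predictor]] = None,
              params: FitParams = FitParams(),
              y: Optional[np.ndarray] = None,
              weights: Optional[np.ndarray] = None,
              provenance: Optional[dict] = None) -> FittedTree:
    """Grow a conditional inference tree on a cohort.

    The endpoint defaults to the binarized PT-WBS outcome of the cohort.
    Growth is depth-first; a node becomes terminal when it is pure, when
    its weight falls below ``minsplit``, when no admissible cutpoint
    exists, or when no predictor reaches significance after Bonferroni
    adjustment.
    """
    if isinstance(data, Cohort):
        df = data.df
        if y is None:
            y = data.endpoint
    else:
        df = data
        if y is None:
            y = (df["ptwbs"].to_numpy() == "positive").astype(np.int64)
    if len(df) == 0:
        raise ValueError("cannot fit a tree on an empty cohort")
    preds = list(predictors) if predictors is not None else default_predictors()
    y = np.asarray(y, dtype=float)
    w = np.ones(len(df)) if weights is None else np.asarray(weights, dtype=float)

    enc = {p.name: _encode(df, p) for p in preds}
    counter = {"id": 0}

    def next_id() -> int:
        counter["id"] += 1
        return counter["id"]

    def terminal(idx: np.ndarray) -> Terminal:
        W = float(w[idx].sum())
        return Terminal(next_id(), W, float((w[idx] * y[idx]).sum() / W))

    def node_select(idx: np.ndarray) -> Optional[tuple[Predictor, float]]:
        best = None
        for pred in preds:
            e = enc[pred.name][idx]
            x = _indicator(e, len(pred.levels)) if pred.kind == "nominal" else e
            res = association_test(x, y[idx], w[idx])
            if best is None or res.p_value < best[1]:
                best = (pred, res.p_value)
        p_adj = min(1.0, len(preds) * best[1])
        return None if p_adj > params.alpha else (best[0], p_adj)

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        W = float(w[idx].sum())
        _, _, V = _moments(y[idx], w[idx])
        if (W < params.minsplit or V <= 0
                or (params.max_depth is not None and depth >= params.max_depth)):
            return terminal(idx)
        sel = node_select(idx)
        if sel is None:
            return terminal(idx)
        pred, p_adj = sel
        e = enc[pred.name][idx]
        if pred.kind == "nominal":
            found = find_level_split(e, pred.levels, y[idx], w[idx], params)
            if found is None:
                return terminal(idx)
            subset, stat = found
            members = [list(pred.levels).index(v) for v in subset]
            left_mask = np.isin(e, members)
            cut = None
        else:
            found = find_cutpoint(e, y[idx], w[idx], params)
            if found is None:
                return terminal(idx)
            cut, stat = found
            left_mask = e <= cut
            subset = None
        nid = next_id()
        left = grow(idx[left_mask], depth + 1)
        right = grow(idx[~left_mask], depth + 1)
        return Split(nid, pred.name, cut, subset, p_adj, stat, left, right)

    root = grow(np.arange(len(df)), 0)
    _renumber_preorder(root)
    return FittedTree(root, params, preds, provenance or {})


def _renumber_preorder(root: TreeNode) -> None:
    """Stable preorder node ids (root = 1, left subtree before right)."""
    counter = {"id": 0}

    def walk(node: TreeNode) -> None:
        counter["id"] += 1
        node.node_id = counter["id"]
        if not node.is_terminal:
            walk(node.left)
            walk(node.right)

    walk(root)


def predict_node(tree: FittedTree, record) -> tuple[int, Optional[float]]:
    """Route one record through the tree; returns (terminal id, risk)."""
    from dataclasses import asdict, is_dataclass

    if is_dataclass(record):
        record = asdict(record)
    row = pd.DataFrame([record])
    out = tree.predict(row).iloc[0]
    risk = None if np.isnan(out["risk"]) else float(out["risk"])
    return int(out["node_id"]), risk
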