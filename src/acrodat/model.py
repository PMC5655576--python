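"""The disease-activity algorithm: gate, CART, two-stage logistic, score.

The algorithm classifies a five-parameter severity level vector into
S / M-DA / S-DA and produces a continuous 0-1 disease-activity score:

1. **Non-compensatory gate** — IGF-I at level 3 or tumor status at level 3
   forces S-DA regardless of the other parameters.  The validation survey's
   CART analysis showed these two parameters dominate physician judgment
   with no opportunity for the others to compensate.
2. **Two-stage logistic model** below the gate — Model 1 predicts whether
   the physician rates the scenario stable (S vs not); Model 2, fit on the
   non-stable ratings only, predicts S-DA vs M-DA.  Covariates are
   indicator-coded severity levels (reference level 1), by default for the
   three compensatory parameters (comorbidities, symptoms, QoL), optionally
   for all five.
3. **Probability combination** — *literal* mode takes P_S from Model 1 and
   P_S-DA from Model 2 and sets P_M-DA = 1 - P_S - P_S-DA (clamping a
   negative remainder to 0 and renormalizing, with a coherence warning);
   *conditional* mode treats Model 2 as P(S-DA | not S), which can never go
   negative.
4. **Score** — ACRODAT score = ([1*P_S + 2*P_M-DA + 3*P_S-DA] - 1) / 2,
   the expected severity rescaled to [0, 1].
5. **Classification** below the gate: M-DA if P_M-DA > P_S, S if
   P_S > P_M-DA (ties resolve to M-DA, the cautious direction).

Gate-triggered vectors report class S-DA with score 1.0 by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .agreement import CATEGORIES
from .errors import (
    ConvergenceError,
    DegenerateModelError,
    GateViolationError,
    NotFittedError,
    CoherenceWarning,
    ValidationError,
)
from .scenario import (
    LevelVector,
    N_SCENARIOS,
    PARAM_NAMES,
    decode_scenario,
    enumerate_scenarios,
)

__all__ = [
    "ActivityProbabilities",
    "CovariateCoding",
    "LogisticSubmodel",
    "DecisionTreeNode",
    "TwoStageActivityClassifier",
    "GiniCartClassifier",
    "THREE_PARAM_CODING",
    "FIVE_PARAM_CODING",
    "is_gated",
    "code_covariates",
    "fit_two_stage",
    "fit_cart",
    "combine_probabilities",
    "acrodat_score",
    "classify",
    "score_all_scenarios",
]


class ActivityProbabilities(NamedTuple):
    """Probability of each disease-activity category; sums to 1."""

    p_s: float
    p_mda: float
    p_sda: float


# ---------------------------------------------------------------------------
# covariate coding

@dataclass(frozen=True)
class CovariateCoding:
    """Indicator coding of severity levels, reference level 1.

    Each included 3-level parameter contributes two indicator columns
    (level == 2, level == 3); the stable reference level is not coded.
    Full five-parameter coding therefore has 10 columns.
    """

    included_params: tuple[str, ...]

    def __post_init__(self):
        params = tuple(self.included_params)
        unknown = [p for p in params if p not in PARAM_NAMES]
        if unknown or len(set(params)) != len(params) or not params:
            raise ValidationError(
                f"included_params must be distinct names from {PARAM_NAMES}; got {params}"
            )
        object.__setattr__(self, "included_params", params)

    @classmethod
    def from_name(cls, name: str) -> "CovariateCoding":
        if name == "three_param":
            return THREE_PARAM_CODING
        if name == "five_param":
            return FIVE_PARAM_CODING
        raise ValidationError(f"unknown coding {name!r}; use 'three_param' or 'five_param'")

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(f"{p}_{lvl}" for p in self.included_params for lvl in (2, 3))

    @property
    def n_columns(self) -> int:
        return 2 * len(self.included_params)

    def design_matrix(self, X: np.ndarray) -> np.ndarray:
        """Indicator matrix for an (n, 5) array of severity levels."""
        X = _validate_levels(X)
        cols = []
        for p in self.included_params:
            j = PARAM_NAMES.index(p)
            cols.append((X[:, j] == 2).astype(float))
            cols.append((X[:, j] == 3).astype(float))
        return np.column_stack(cols) if cols else np.zeros((len(X), 0))


#: Compensatory parameters only (the default, matching the published model).
THREE_PARAM_CODING = CovariateCoding(("comorbidity", "symptoms", "qol"))
#: All five parameters (adds the sub-gate IGF-I and tumor level-2 effects).
FIVE_PARAM_CODING = CovariateCoding(PARAM_NAMES)


def code_covariates(v: Sequence[int], coding: CovariateCoding) -> np.ndarray:
    """Indicator row for one level vector under ``coding``."""
    return coding.design_matrix(np.asarray(v, dtype=int).reshape(1, 5))[0]


def _validate_levels(X) -> np.ndarray:
    X = np.asarray(X, dtype=int)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.ndim != 2 or X.shape[1] != 5:
        raise ValidationError(f"level array must have 5 columns; got shape {X.shape}")
    if not np.isin(X, (1, 2, 3)).all():
        raise ValidationError("severity levels must be 1, 2 or 3")
    return X


def is_gated(v: Sequence[int]) -> bool:
    """True if the non-compensatory gate fires (IGF-I or tumor at level 3)."""
    v = _validate_levels(v)[0]
    return bool(v[0] == 3 or v[1] == 3)


def _gate_mask(X: np.ndarray) -> np.ndarray:
    return (X[:, 0] == 3) | (X[:, 1] == 3)


# ---------------------------------------------------------------------------
# logistic submodels

@dataclass(frozen=True)
class LogisticSubmodel:
    """One fitted binary logistic stage (penalized ML)."""

    coding: CovariateCoding
    intercept: float
    coefficients: np.ndarray
    converged: bool
    ridge: float
    n_obs: int = 0

    def __post_init__(self):
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.shape != (self.coding.n_columns,):
            raise ValidationError(
                f"expected {self.coding.n_columns} coefficients; got {coef.shape}"
            )
        object.__setattr__(self, "coefficients", coef)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Event probability for an (n, 5) level array."""
        Z = self.coding.design_matrix(X)
        return expit(self.intercept + Z @ self.coefficients)


def _fit_binary(
    X: np.ndarray, y01: np.ndarray, coding: CovariateCoding, ridge: float, max_iter: int
) -> LogisticSubmodel:
    if ridge < 0:
        raise ValidationError("ridge strength must be >= 0")
    classes = np.unique(y01)
    Z = coding.design_matrix(X)
    if len(classes) == 1:
        # one-sided outcome: intercept at the smoothed base-rate logit
        p = (y01.sum() + 0.5) / (len(y01) + 1.0)
        return LogisticSubmodel(
            coding=coding,
            intercept=float(np.log(p / (1 - p))),
            coefficients=np.zeros(coding.n_columns),
            converged=True,
            ridge=ridge,
            n_obs=len(y01),
        )
    kwargs = dict(solver="lbfgs", max_iter=max_iter, tol=1e-8)
    if ridge == 0:
        clf = LogisticRegression(penalty=None, **kwargs)
    else:
        clf = LogisticRegression(penalty="l2", C=1.0 / ridge, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence handled explicitly below
        clf.fit(Z, y01)
    converged = int(clf.n_iter_[0]) < max_iter
    if not converged:
        hint = "; refit with ridge > 0 (data may be completely separated)" if ridge == 0 else ""
        raise ConvergenceError(
            f"logistic stage did not converge in {max_iter} iterations{hint}"
        )
    return LogisticSubmodel(
        coding=coding,
        intercept=float(clf.intercept_[0]),
        coefficients=clf.coef_[0].copy(),
        converged=True,
        ridge=ridge,
        n_obs=len(y01),
    )


# ---------------------------------------------------------------------------
# the deployable two-stage classifier

class TwoStageActivityClassifier(BaseEstimator, ClassifierMixin):
    """Gated two-stage logistic classifier of disease activity.

    Parameters
    ----------
    coding : {'three_param', 'five_param'} or CovariateCoding, default 'three_param'
        Which severity parameters enter the logistic stages as indicators.
        ``three_param`` uses the compensatory parameters (comorbidities,
        symptoms, QoL); ``five_param`` adds the IGF-I and tumor level-2
        indicators (their level-3 rows never reach the stages).
    mode : {'literal', 'conditional'}, default 'literal'
        How Model 2's prediction enters the probability triple.  ``literal``
        treats it as the unconditional P(S-DA), deriving P(M-DA) as the
        remainder (clamped at 0 with a :class:`CoherenceWarning` if
        negative); ``conditional`` treats it as P(S-DA | not stable), which
        is always coherent.
    ridge : float, default 1e-6
        L2 penalty strength on the stage coefficients; a small default keeps
        the fits finite under the quasi-separation typical of small vignette
        datasets.
    max_iter : int, default 100
        Iteration cap per logistic stage.

    Attributes
    ----------
    classes_ : ndarray of the three category labels ('S', 'M-DA', 'S-DA').
    model1_, model2_ : the fitted :class:`LogisticSubmodel` stages.
    n_gated_, n_retained_ : training rows removed by / surviving the gate.
    """

    def __init__(self, coding="three_param", mode="literal", ridge=1e-6, max_iter=100):
        self.coding = coding
        self.mode = mode
        self.ridge = ridge
        self.max_iter = max_iter

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        """Fit both stages on (level-vector, rating) data.

        Gate-triggering rows (IGF-I or tumor at level 3) are excluded
        before fitting: the logistic stages model only the compensatory
        region of the scenario space.
        """
        X = _validate_levels(X)
        y = np.asarray(y, dtype=object)
        if len(y) != len(X):
            raise ValidationError("X and y length mismatch")
        bad = ~np.isin(y, CATEGORIES)
        if bad.any():
            raise ValidationError(f"unknown rating label {y[bad][0]!r}")
        if self.mode not in ("literal", "conditional"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        coding = (
            self.coding
            if isinstance(self.coding, CovariateCoding)
            else CovariateCoding.from_name(self.coding)
        )

        gate = _gate_mask(X)
        Xr, yr = X[~gate], y[~gate]
        if len(Xr) == 0:
            raise DegenerateModelError("no non-gate rows to fit the logistic stages on")

        y1 = (yr == "S").astype(int)
        self.model1_ = _fit_binary(Xr, y1, coding, self.ridge, self.max_iter)

        non_s = yr != "S"
        if not non_s.any():
            raise DegenerateModelError(
                "second stage degenerate: no non-stable ratings below the gate"
            )
        y2 = (yr[non_s] == "S-DA").astype(int)
        self.model2_ = _fit_binary(Xr[non_s], y2, coding, self.ridge, self.max_iter)

        self.coding_ = coding
        self.classes_ = np.array(CATEGORIES, dtype=object)
        self.n_gated_ = int(gate.sum())
        self.n_retained_ = int(len(Xr))
        self.n_clamped_ = 0
        return self

    def _check_fitted(self):
        if not hasattr(self, "model1_"):
            raise NotFittedError("call fit() before predicting")

    # -- probability machinery --------------------------------------------

    def _combine(self, X: np.ndarray) -> np.ndarray:
        """(n, 3) probability triples for non-gate rows, in category order."""
        p1 = self.model1_.predict(X)
        p2 = self.model2_.predict(X)
        if self.mode == "conditional":
            p_s = p1
            p_sda = (1.0 - p1) * p2
            p_mda = (1.0 - p1) * (1.0 - p2)
        else:
            p_s = p1.copy()
            p_sda = p2.copy()
            p_mda = 1.0 - p_s - p_sda
            neg = p_mda < 0
            if neg.any():
                self.n_clamped_ += int(neg.sum())
                warnings.warn(
                    f"literal combination produced a negative M-DA probability for "
                    f"{int(neg.sum())} row(s); clamped to 0 and renormalized",
                    CoherenceWarning,
                    stacklevel=3,
                )
                p_mda[neg] = 0.0
                total = p_s[neg] + p_sda[neg]
                p_s[neg] /= total
                p_sda[neg] /= total
        return np.column_stack([p_s, p_mda, p_sda])

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities in ``classes_`` order; gate rows are (0, 0, 1)."""
        self._check_fitted()
        X = _validate_levels(X)
        out = np.zeros((len(X), 3))
        gate = _gate_mask(X)
        out[gate, 2] = 1.0
        if (~gate).any():
            out[~gate] = self._combine(X[~gate])
        return out

    def predict(self, X) -> np.ndarray:
        """Activity class per row: gate rows S-DA; otherwise the published
        rule comparing P_S with P_M-DA (ties to M-DA)."""
        self._check_fitted()
        X = _validate_levels(X)
        proba = self.predict_proba(X)
        gate = _gate_mask(X)
        labels = np.where(proba[:, 0] > proba[:, 1], "S", "M-DA").astype(object)
        labels[gate] = "S-DA"
        return labels

    def acrodat_scores(self, X) -> np.ndarray:
        """Continuous 0-1 scores; gate rows report 1.0 by convention."""
        proba = self.predict_proba(X)
        scores = (proba @ np.array([1.0, 2.0, 3.0]) - 1.0) / 2.0
        scores[_gate_mask(_validate_levels(X))] = 1.0
        return scores

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-serializable snapshot of the fitted model."""
        self._check_fitted()

        def stage(m: LogisticSubmodel) -> dict:
            return {
                "intercept": m.intercept,
                "coefficients": m.coefficients.tolist(),
                "converged": m.converged,
                "n_obs": m.n_obs,
            }

        return {
            "model": "two_stage_activity",
            "gate": "igf==3 or tumor==3 -> S-DA",
            "coding": list(self.coding_.included_params),
            "mode": self.mode,
            "ridge": self.ridge,
            "model1": stage(self.model1_),
            "model2": stage(self.model2_),
            "n_gated": self.n_gated_,
            "n_retained": self.n_retained_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoStageActivityClassifier":
        """Rebuild a fitted model from :meth:`to_dict` output."""
        coding = CovariateCoding(tuple(d["coding"]))
        est = cls(coding=coding, mode=d["mode"], ridge=d["ridge"])
        for key in ("model1", "model2"):
            s = d[key]
            sub = LogisticSubmodel(
                coding=coding,
                intercept=float(s["intercept"]),
                coefficients=np.asarray(s["coefficients"], dtype=float),
                converged=bool(s["converged"]),
                ridge=float(d["ridge"]),
                n_obs=int(s.get("n_obs", 0)),
            )
            setattr(est, f"{key}_", sub)
        est.coding_ = coding
        est.classes_ = np.array(CATEGORIES, dtype=object)
        est.n_gated_ = int(d.get("n_gated", 0))
        est.n_retained_ = int(d.get("n_retained", 0))
        est.n_clamped_ = 0
        return est


# ---------------------------------------------------------------------------
# CART

@dataclass
class DecisionTreeNode:
    """One node of the Gini CART over the five ordinal parameters.

    Internal nodes split one parameter on an ordered level subset
    ({1} vs {2,3} or {1,2} vs {3}); ``left`` receives the rows whose level
    lies in ``levels_left``.  Leaves carry the class distribution (category
    order S, M-DA, S-DA) and the majority prediction.
    """

    n_samples: int
    class_distribution: tuple[float, float, float]
    prediction: str
    param: Optional[str] = None
    levels_left: Optional[frozenset] = None
    left: Optional["DecisionTreeNode"] = None
    right: Optional["DecisionTreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.param is None

    def predict(self, v: Sequence[int]) -> str:
        node = self
        v = _validate_levels(v)[0]
        while not node.is_leaf:
            j = PARAM_NAMES.index(node.param)
            node = node.left if v[j] in node.levels_left else node.right
        return node.prediction


class GiniCartClassifier(BaseEstimator, ClassifierMixin):
    """Greedy binary CART on the five ordinal severity parameters.

    A thin, inspectable wrapper over a Gini decision tree: because the
    parameters are ordered 3-level factors, every binary threshold split
    is exactly one of the ordered subset splits {1} vs {2,3} or
    {1,2} vs {3}.  Exposes the tree as a :class:`DecisionTreeNode` chain
    in ``root_``.
    """

    def __init__(self, min_leaf: int = 20):
        self.min_leaf = min_leaf

    def fit(self, X, y):
        X = _validate_levels(X)
        y = np.asarray(y, dtype=object)
        if len(X) == 0:
            raise ValidationError("cannot grow a tree on empty data")
        if self.min_leaf < 1:
            raise ValidationError("min_leaf must be >= 1")
        bad = ~np.isin(y, CATEGORIES)
        if bad.any():
            raise ValidationError(f"unknown rating label {y[bad][0]!r}")
        tree = DecisionTreeClassifier(
            criterion="gini", min_samples_leaf=self.min_leaf, random_state=0
        )
        tree.fit(X, y)
        self.tree_ = tree
        self.classes_ = np.array(CATEGORIES, dtype=object)
        self.root_ = self._to_node(tree, 0)
        return self

    def _to_node(self, tree: DecisionTreeClassifier, idx: int) -> DecisionTreeNode:
        t = tree.tree_
        # sklearn stores class counts in lexicographic label order; remap to
        # the domain order S, M-DA, S-DA
        sk_order = list(tree.classes_)
        counts = t.value[idx][0] * t.weighted_n_node_samples[idx]
        dist = np.zeros(3)
        for lab, c in zip(sk_order, counts):
            dist[CATEGORIES.index(lab)] = c
        total = dist.sum()
        dist = dist / total if total else dist
        prediction = CATEGORIES[int(np.argmax(dist))]
        node = DecisionTreeNode(
            n_samples=int(t.n_node_samples[idx]),
            class_distribution=tuple(float(d) for d in dist),
            prediction=prediction,
        )
        if t.children_left[idx] != -1:
            node.param = PARAM_NAMES[int(t.feature[idx])]
            thr = float(t.threshold[idx])
            node.levels_left = frozenset({1} if thr < 2 else {1, 2})
            node.left = self._to_node(tree, int(t.children_left[idx]))
            node.right = self._to_node(tree, int(t.children_right[idx]))
        return node

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "root_"):
            raise NotFittedError("call fit() before predicting")
        X = _validate_levels(X)
        return np.array([self.root_.predict(v) for v in X], dtype=object)


# ---------------------------------------------------------------------------
# functional surface

def fit_two_stage(
    data: Sequence[tuple[Sequence[int], str]],
    coding="three_param",
    ridge: float = 1e-6,
    mode: str = "literal",
) -> TwoStageActivityClassifier:
    """Fit the gated two-stage model from (level-vector, rating) pairs."""
    X = np.array([tuple(v) for v, _ in data], dtype=int)
    y = np.array([c for _, c in data], dtype=object)
    return TwoStageActivityClassifier(coding=coding, mode=mode, ridge=ridge).fit(X, y)


def fit_cart(
    data: Sequence[tuple[Sequence[int], str]], min_leaf: int = 20
) -> DecisionTreeNode:
    """Grow the Gini CART from (level-vector, rating) pairs; returns the root."""
    X = np.array([tuple(v) for v, _ in data], dtype=int)
    y = np.array([c for _, c in data], dtype=object)
    return GiniCartClassifier(min_leaf=min_leaf).fit(X, y).root_


def combine_probabilities(
    m: TwoStageActivityClassifier, v: Sequence[int]
) -> ActivityProbabilities:
    """The (P_S, P_M-DA, P_S-DA) triple for one non-gate level vector."""
    m._check_fitted()
    if is_gated(v):
        raise GateViolationError(
            f"level vector {tuple(v)} triggers the gate; use classify() instead"
        )
    row = m._combine(_validate_levels(v))[0]
    return ActivityProbabilities(*[float(p) for p in row])


def acrodat_score(p: Sequence[float]) -> float:
    """ACRODAT score ([1*P_S + 2*P_M-DA + 3*P_S-DA] - 1) / 2 on [0, 1]."""
    p = np.asarray(p, dtype=float)
    if p.shape != (3,) or (p < -1e-12).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError(
            f"expected a normalized probability triple; got {p.tolist()}"
        )
    return float((p @ [1.0, 2.0, 3.0] - 1.0) / 2.0)


def classify(
    m: TwoStageActivityClassifier, v: Sequence[int]
) -> tuple[str, ActivityProbabilities | str, float]:
    """Full per-vector result: (class, probabilities or 'gate', score)."""
    m._check_fitted()
    if is_gated(v):
        return ("S-DA", "gate", 1.0)
    probs = combine_probabilities(m, v)
    label = "S" if probs.p_s > probs.p_mda else "M-DA"
    return (label, probs, acrodat_score(probs))


def score_all_scenarios(m: TwoStageActivityClassifier):
    """Deterministic report over the full 243-scenario grid."""
    import pandas as pd

    m._check_fitted()
    rows = []
    for sid, v in enumerate_scenarios():
        if is_gated(v):
            rows.append((sid, v.code, "S-DA", 0.0, 0.0, 1.0, 1.0, True))
        else:
            label, p, score = classify(m, v)
            rows.append((sid, v.code, label, p.p_s, p.p_mda, p.p_sda, score, False))
    return pd.DataFrame(
        rows,
        columns=[
            "scenario_id", "code", "activity_class",
            "p_s", "p_mda", "p_sda", "score", "gated",
        ],
    )
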