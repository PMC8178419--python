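"""Two-stage LASSO discrimination cascade for loop-mutant prioritization.

The screen's thermostability activities are stratified into high / medium /
low tertiles by rank.  Two L1-penalised binary discriminators are then
fitted on the 39 standardized physicochemical features:

* stage 1 — "improved" (high + medium) versus "non-improved" (low), used
  to discard unpromising candidate triples;
* stage 2 — "high" versus "medium" improvement, whose predicted
  probability of the high class ranks the surviving candidates.

Both models are validated by leave-one-out cross-validation, all unobserved
residue triples in the 20^3 space are synthesized in silico, screened by
stage 1 (keep if P(improved) > 0.5) and ranked by stage 2.

The user-facing entry points are :class:`ThermostabilityCascade` (the model,
built from triples + activities) and :class:`CascadeResults` (returned by
``fit``; carries the fitted discriminators, LOOCV reports, ranking and
weight table).  The stage functions underneath are exported for stage-wise
use and testing.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV, LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import l1_min_c

from .descriptors import (
    ALPHABET,
    DescriptorTable,
    ScalerParams,
    apply_scaler,
    encode_library,
    fit_scaler,
)
from .screening import MutantRecord, thermostability_activity

__all__ = [
    "StratificationConfig",
    "stratify_by_tertiles",
    "DiscriminationModel",
    "fit_lasso_discriminator",
    "LoocvReport",
    "loocv",
    "enumerate_candidate_triples",
    "screen_stage1",
    "rank_stage2",
    "CandidateRanking",
    "select_top_candidates",
    "extract_weight_table",
    "ThermostabilityCascade",
    "CascadeResults",
]

LABEL_HIGH, LABEL_MEDIUM, LABEL_LOW = "high", "medium", "low"

#: Decades of the regularisation path below lambda_max, and its length.
#: The path starts at the smallest C with any active feature (lambda_max)
#: and descends lambda by this many decades, glmnet-style; ties in
#: cross-validated deviance resolve toward the sparser (smaller C) end.
_PATH_DECADES = 2.5
_PATH_POINTS = 6

#: liblinear appends the intercept as a pseudo-feature of this magnitude;
#: a large value leaves the intercept effectively unpenalised, as in the
#: textbook L1-logistic objective.
_INTERCEPT_SCALING = 1000.0


# ---------------------------------------------------------------------- #
# tertile stratification


@dataclass(frozen=True)
class StratificationConfig:
    """Tail fractions for rank-based tertile stratification."""

    top_fraction: float = 0.34
    bottom_fraction: float = 0.34

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction and 0 < self.bottom_fraction):
            raise ValueError("stratification fractions must be positive")
        if self.top_fraction + self.bottom_fraction >= 1:
            raise ValueError(
                "top_fraction + bottom_fraction must be < 1 "
                f"(got {self.top_fraction} + {self.bottom_fraction})"
            )


def stratify_by_tertiles(
    activities: Sequence[float], config: StratificationConfig | None = None
) -> np.ndarray:
    """Label activities high / medium / low by descending rank.

    The top ``ceil(top_fraction * n)`` records are labelled high, the
    bottom ``ceil(bottom_fraction * n)`` low, the remainder medium.  Ties
    are broken by stable input order.  With the default 34% / 34% tails and
    n = 214 the quota arithmetic gives 73 high, 73 low and 68 medium; the
    counts are reported as computed, never adjusted.
    """
    config = config or StratificationConfig()
    act = np.asarray(list(activities), float)
    n = act.shape[0]
    if n < 3:
        raise ValueError(f"stratification requires n >= 3, got {n}")
    if not np.isfinite(act).all():
        raise ValueError("activities must be finite")
    n_high = math.ceil(config.top_fraction * n)
    n_low = math.ceil(config.bottom_fraction * n)
    if n_high + n_low > n:
        raise ValueError("tail quotas exceed the number of records")
    order = np.argsort(-act, kind="stable")  # descending, ties by input order
    labels = np.full(n, LABEL_MEDIUM, dtype=object)
    labels[order[:n_high]] = LABEL_HIGH
    labels[order[n - n_low :]] = LABEL_LOW
    return labels


# ---------------------------------------------------------------------- #
# L1-penalised discriminators


@dataclass(frozen=True)
class DiscriminationModel:
    """A fitted sparse binary discriminator on standardized features.

    ``weights`` and ``intercept`` parameterise the decision function on
    standardized features; positive weights are evidence for
    ``positive_label``.  ``regularization_strength`` is the L1 penalty
    lambda (= 1/C for the logistic family).
    """

    contrast: str
    positive_label: str
    negative_label: str
    weights: np.ndarray
    intercept: float
    regularization_strength: float
    scaler: ScalerParams
    family: str = "logistic"
    training_meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = apply_scaler(X, self.scaler)
        if Xs.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension mismatch: {Xs.shape[1]} != {self.n_features}"
            )
        return Xs @ self.weights + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of ``positive_label`` for each row of raw features."""
        z = self.decision_function(X)
        if self.family == "logistic":
            return 1.0 / (1.0 + np.exp(-z))
        # linear-on-labels variant: the fitted value approximates the class
        # probability; clip into (0, 1)
        return np.clip(z, 1e-9, 1.0 - 1e-9)

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        return np.where(p > 0.5, self.positive_label, self.negative_label)


def _parse_lambda_policy(policy: str) -> tuple[str, float | int]:
    if policy.startswith("fixed:"):
        lam = float(policy.split(":", 1)[1])
        if lam <= 0:
            raise ValueError("fixed lambda must be > 0")
        return "fixed", lam
    if policy.startswith("cv") and policy[2:].isdigit():
        k = int(policy[2:])
        if k < 2:
            raise ValueError("cross-validated lambda policy needs >= 2 folds")
        return "cv", k
    raise ValueError(
        f"unknown lambda policy {policy!r}; expected 'cv<k>' or 'fixed:<lambda>'"
    )


def _l1_logistic(C: float, tol: float = 1e-8, max_iter: int = 20000) -> LogisticRegression:
    return LogisticRegression(
        C=C,
        l1_ratio=1.0,  # pure L1 penalty
        solver="liblinear",
        intercept_scaling=_INTERCEPT_SCALING,
        tol=tol,
        max_iter=max_iter,
        random_state=0,  # liblinear shuffles rows; pin for bit-reproducibility
    )


def _candidate_C_path(Xs: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Data-adaptive C path from lambda_max down, glmnet-style.

    Anchoring the path at ``l1_min_c`` (the largest penalty at which any
    feature becomes active) keeps the search away from the near-unpenalised
    regime, where L1-logistic solvers stall on nearly separable screens.
    """
    c_min = float(l1_min_c(Xs, y01, loss="log"))
    return c_min * np.logspace(0.0, _PATH_DECADES, _PATH_POINTS)


def _select_C_by_cv(Xs: np.ndarray, y01: np.ndarray, n_folds: int, seed: int) -> float:
    """Pick C on the adaptive path by k-fold cross-validated deviance.

    Folds are stratified with a seeded shuffle; k is capped at the smaller
    class count.  If a class is too small for 2-fold CV, C = 1 is used.
    Deviance ties resolve toward the smaller C (stronger penalty).  Search
    fits use a relaxed tolerance; only the final refit is tight.
    """
    min_class = int(np.bincount(y01).min())
    k = min(n_folds, min_class)
    if k < 2:
        return 1.0
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(cv.split(Xs, y01))
    grid = _candidate_C_path(Xs, y01)
    mean_loss = []
    with warnings.catch_warnings():
        # search fits are deliberately loose (tol 1e-4, capped iterations);
        # only their relative deviances matter, so iteration caps are fine
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        for C in grid:
            losses = []
            for train, test in folds:
                clf = _l1_logistic(C, tol=1e-4, max_iter=2000).fit(
                    Xs[train], y01[train]
                )
                p = clf.predict_proba(Xs[test])[:, 1]
                losses.append(log_loss(y01[test], p, labels=[0, 1]))
            mean_loss.append(float(np.mean(losses)))
    return float(grid[int(np.argmin(mean_loss))])


def fit_lasso_discriminator(
    X: np.ndarray,
    y: Sequence[str],
    *,
    positive_label: str,
    contrast: str = "binary",
    lambda_policy: str = "cv5",
    family: str = "logistic",
    seed: int = 0,
    scaler: ScalerParams | None = None,
) -> DiscriminationModel:
    """Fit an L1-penalised binary discriminator on raw features.

    Features are standardized (scaler fitted here unless supplied) because
    the L1 penalty is scale-sensitive.  The penalty lambda comes from the
    ``lambda_policy``: ``"cv<k>"`` picks it by k-fold cross-validated
    deviance along a data-adaptive path from lambda_max (glmnet-style) with a seeded shuffle, ``"fixed:<lambda>"``
    uses the given value.  ``family="logistic"`` (default) fits L1 logistic
    discrimination; ``family="linear"`` fits an L1 linear regression on 0/1
    labels, exposed for sensitivity analysis.
    """
    X = np.asarray(X, float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    y = np.asarray(list(y))
    classes = pd.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if positive_label not in classes:
        raise ValueError(f"positive_label {positive_label!r} not among {list(classes)}")
    negative_label = next(c for c in classes if c != positive_label)
    y01 = (y == positive_label).astype(int)

    if scaler is None:
        scaler = fit_scaler(X)
    Xs = apply_scaler(X, scaler)

    mode, value = _parse_lambda_policy(lambda_policy)
    if family == "logistic":
        if mode == "cv":
            C = _select_C_by_cv(Xs, y01, n_folds=int(value), seed=seed)
        else:
            C = 1.0 / value
        est = _l1_logistic(C).fit(Xs, y01)
        weights = est.coef_.ravel().copy()
        intercept = float(est.intercept_[0])
        lam = 1.0 / C
    elif family == "linear":
        if mode == "cv":
            k = int(min(value, len(y01)))
            est = LassoCV(cv=k, random_state=seed, max_iter=20000).fit(Xs, y01)
            lam = float(est.alpha_)
        else:
            lam = value
            est = Lasso(alpha=lam, max_iter=20000).fit(Xs, y01)
        weights = np.asarray(est.coef_, float).copy()
        intercept = float(est.intercept_)
    else:
        raise ValueError(f"unknown family {family!r}")

    counts = {str(c): int((y == c).sum()) for c in classes}
    return DiscriminationModel(
        contrast=contrast,
        positive_label=str(positive_label),
        negative_label=str(negative_label),
        weights=weights,
        intercept=intercept,
        regularization_strength=lam,
        scaler=scaler,
        family=family,
        training_meta={
            "n": int(len(y)),
            "label_counts": counts,
            "seed": int(seed),
            "lambda_policy": lambda_policy,
        },
    )


# ---------------------------------------------------------------------- #
# leave-one-out cross-validation


@dataclass(frozen=True)
class LoocvReport:
    """Held-out prediction for every training sample."""

    per_sample: pd.DataFrame  # columns: true, predicted, p_positive, degenerate_fold

    @property
    def accuracy(self) -> float:
        return float((self.per_sample["true"] == self.per_sample["predicted"]).mean())

    @property
    def n(self) -> int:
        return len(self.per_sample)


def loocv(
    X: np.ndarray,
    y: Sequence[str],
    fit_procedure: Callable[[np.ndarray, np.ndarray], DiscriminationModel],
) -> LoocvReport:
    """Leave-one-out validation: refit on n-1 samples, predict the held-out one.

    The lambda policy embedded in ``fit_procedure`` is re-applied inside each
    fold.  A fold that would lose one class entirely is predicted by the
    majority class of the remaining samples and flagged.
    """
    X = np.asarray(X, float)
    y = np.asarray(list(y))
    n = len(y)
    if n < 2 or len(pd.unique(y)) != 2:
        raise ValueError("LOOCV needs n >= 2 samples from exactly 2 classes")
    rows = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        y_train = y[mask]
        classes, counts = np.unique(y_train, return_counts=True)
        if len(classes) < 2:
            majority = classes[np.argmax(counts)]
            rows.append((y[i], majority, np.nan, True))
            continue
        model = fit_procedure(X[mask], y_train)
        pred = model.predict_label(X[i : i + 1])[0]
        p = float(model.predict_proba(X[i : i + 1])[0])
        rows.append((y[i], pred, p, False))
    per_sample = pd.DataFrame(
        rows, columns=["true", "predicted", "p_positive", "degenerate_fold"]
    )
    return LoocvReport(per_sample=per_sample)


# ---------------------------------------------------------------------- #
# in silico candidate space


def _validate_triples(triples: Iterable[str], alphabet: str) -> list[str]:
    out = []
    for t in triples:
        t = "".join(t)
        if len(t) != 3 or any(c not in alphabet for c in t):
            raise ValueError(f"invalid residue triple {t!r} for alphabet {alphabet!r}")
        out.append(t)
    return out


def _alphabet_key(triple: str, alphabet: str = ALPHABET) -> tuple[int, ...]:
    return tuple(alphabet.index(c) for c in triple)


def enumerate_candidate_triples(
    observed: Iterable[str], alphabet: str = ALPHABET
) -> list[str]:
    """All unobserved triples of the combinatorial space, in alphabet order.

    With the 20-letter alphabet the full space has 20^3 = 8000 members;
    removing a screen of 214 distinct observed triples leaves 7786
    candidates.  Order is lexicographic in the fixed alphabet order.
    """
    seen = set(_validate_triples(observed, alphabet))
    return [
        "".join(t)
        for t in itertools.product(alphabet, repeat=3)
        if "".join(t) not in seen
    ]


def screen_stage1(
    model: DiscriminationModel, candidates: Sequence[str], features: np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Keep candidates the improved/non-improved model calls improved.

    ``features`` are raw (unstandardized) encodings aligned with
    ``candidates``; the model applies its stored scaler.  A candidate is
    kept iff P(improved) > 0.5; enumeration order is preserved.  Returns
    the kept triples and the full probability vector (all candidates).
    """
    p = model.predict_proba(np.asarray(features, float))
    kept = [c for c, pi in zip(candidates, p) if pi > 0.5]
    return kept, p


@dataclass(frozen=True)
class CandidateRanking:
    """Candidates ordered by predicted probability of the high class."""

    entries: pd.DataFrame  # columns: rank, triple, p_high, p_improved

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        df = self.entries.copy()
        out = pd.DataFrame(
            {
                "rank": df["rank"],
                "pos1": [t[0] for t in df["triple"]],
                "pos2": [t[1] for t in df["triple"]],
                "pos3": [t[2] for t in df["triple"]],
                "p_high": df["p_high"].map("{:.10g}".format),
                "stage1_p_improved": df["p_improved"].map("{:.10g}".format),
            }
        )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CandidateRanking":
        df = pd.read_csv(path, sep="\t", dtype={"pos1": str, "pos2": str, "pos3": str})
        entries = pd.DataFrame(
            {
                "rank": df["rank"].astype(int) if len(df) else pd.Series(dtype=int),
                "triple": df["pos1"] + df["pos2"] + df["pos3"],
                "p_high": df["p_high"].astype(float),
                "p_improved": df["stage1_p_improved"].astype(float),
            }
        )
        return cls(entries=entries)


def rank_stage2(
    model: DiscriminationModel,
    candidates: Sequence[str],
    features: np.ndarray,
    stage1_p: Sequence[float] | None = None,
) -> CandidateRanking:
    """Rank stage-1 survivors by P(high) from the high/medium model.

    Exact probability ties are broken lexicographically by triple (fixed
    alphabet order); ranks are consecutive from 1.  An empty candidate list
    yields an empty (valid) ranking.
    """
    candidates = list(candidates)
    if len(set(candidates)) != len(candidates):
        raise ValueError("candidate triples must be unique")
    if not candidates:
        entries = pd.DataFrame(columns=["rank", "triple", "p_high", "p_improved"])
        return CandidateRanking(entries=entries)
    p_high = model.predict_proba(np.asarray(features, float))
    p1 = np.full(len(candidates), np.nan) if stage1_p is None else np.asarray(stage1_p, float)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-p_high[i], _alphabet_key(candidates[i])),
    )
    entries = pd.DataFrame(
        {
            "rank": np.arange(1, len(candidates) + 1),
            "triple": [candidates[i] for i in order],
            "p_high": p_high[order],
            "p_improved": p1[order],
        }
    )
    return CandidateRanking(entries=entries)


def select_top_candidates(
    ranking: CandidateRanking, n_high: int, n_medium: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pick the top predicted-high and top predicted-medium candidates.

    The high list is the top ``n_high`` ranking entries; the medium list is
    drawn from entries predicted medium (P(high) <= 0.5), in descending
    P(high).  The lists are disjoint.  Quota shortfalls return what is
    available with a warning.
    """
    df = ranking.entries
    high = df.head(n_high).copy()
    medium_pool = df[(df["p_high"] <= 0.5) & (~df.index.isin(high.index))]
    medium = medium_pool.head(n_medium).copy()
    if len(high) < n_high or len(medium) < n_medium:
        warnings.warn(
            f"selection shortfall: requested {n_high} high / {n_medium} medium, "
            f"got {len(high)} / {len(medium)}",
            stacklevel=2,
        )
    return high, medium


def extract_weight_table(
    model: DiscriminationModel,
    descriptor_names: Sequence[str],
    positions: Sequence[str] = ("pos1", "pos2", "pos3"),
) -> pd.DataFrame:
    """Reshape a model's position-major weight vector into descriptors x positions.

    Positive cells are evidence for the model's positive class (for the
    stage-2 model: high thermostability improvement); features removed by
    the L1 penalty appear as exact zeros.
    """
    d, p = len(descriptor_names), len(positions)
    if model.n_features != d * p:
        raise ValueError(
            f"model has {model.n_features} weights, expected {d} x {p} = {d * p}"
        )
    mat = model.weights.reshape(p, d).T
    return pd.DataFrame(mat, index=list(descriptor_names), columns=list(positions))


# ---------------------------------------------------------------------- #
# model / results objects


class ThermostabilityCascade:
    """The discrimination-cascade model for one mutagenised loop.

    Built from the screen's residue triples and thermostability activities
    (percent retained after heat treatment).  ``fit`` stratifies, trains the
    two discriminators with leave-one-out validation and returns a
    :class:`CascadeResults`.

    Parameters
    ----------
    triples
        Residue triples of the screened mutants (distinct triples may repeat
        only with identical activity).
    activities
        Thermostability activity per mutant, percent.
    descriptor_table
        Physicochemical scales used for encoding; defaults to the packaged
        13-descriptor set (39 features over three positions).
    stratification
        Tail fractions for the tertile labels (default 34% / 34%).
    lambda_policy, family
        Passed to :func:`fit_lasso_discriminator`.
    """

    def __init__(
        self,
        triples: Sequence[str],
        activities: Sequence[float],
        descriptor_table: DescriptorTable | None = None,
        *,
        stratification: StratificationConfig | None = None,
        lambda_policy: str = "cv5",
        family: str = "logistic",
    ):
        table = descriptor_table if descriptor_table is not None else DescriptorTable.paper_set()
        triples = ["".join(t) for t in triples]
        activities = np.asarray(list(activities), float)
        if len(triples) != len(activities):
            raise ValueError("triples and activities must align")
        seen: dict[str, float] = {}
        for t, a in zip(triples, activities):
            if t in seen and seen[t] != a:
                raise ValueError(
                    f"triple {t} carries two different activities ({seen[t]} vs {a})"
                )
            seen[t] = a
        self.descriptor_table = table
        self.triples = triples
        self.activities = activities
        self.features = encode_library(triples, table)
        self.stratification = stratification or StratificationConfig()
        self.lambda_policy = lambda_policy
        self.family = family

    @classmethod
    def from_screen(
        cls,
        records: Sequence[MutantRecord],
        descriptor_table: DescriptorTable | None = None,
        **kwargs,
    ) -> "ThermostabilityCascade":
        """Build from screening records (thermostability activity computed here)."""
        return cls(
            [r.triple for r in records],
            [thermostability_activity(r) for r in records],
            descriptor_table,
            **kwargs,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        descriptor_table: DescriptorTable | None = None,
        activity_col: str = "thermostability_activity",
        **kwargs,
    ) -> "ThermostabilityCascade":
        """Build from a DataFrame with pos1/pos2/pos3 (or triple) + activity columns."""
        if "triple" in df.columns:
            triples = df["triple"].astype(str).tolist()
        else:
            triples = (df["pos1"] + df["pos2"] + df["pos3"]).astype(str).tolist()
        return cls(triples, df[activity_col].to_numpy(float), descriptor_table, **kwargs)

    # ------------------------------------------------------------------ #
    def fit(self, seed: int = 0, run_loocv: bool | Iterable[str] = True) -> "CascadeResults":
        """Stratify, fit both discriminators (optionally with LOOCV).

        ``run_loocv`` may be a bool or a subset of ``{"stage1", "stage2"}``
        naming the models to validate by leave-one-out.
        """
        if run_loocv is True:
            loocv_stages = {"stage1", "stage2"}
        elif run_loocv is False:
            loocv_stages = set()
        else:
            loocv_stages = set(run_loocv)
        labels = stratify_by_tertiles(self.activities, self.stratification)
        X = self.features.to_numpy(float)

        y1 = np.where(labels == LABEL_LOW, "non-improved", "improved")
        stage1 = self._fit(X, y1, "improved", "improved_vs_nonimproved", seed)

        hm = labels != LABEL_LOW
        y2 = labels[hm]
        stage2 = self._fit(X[hm], y2, LABEL_HIGH, "high_vs_medium", seed)

        loocv1 = loocv2 = None
        if "stage1" in loocv_stages:
            loocv1 = loocv(
                X, y1, lambda Xt, yt: self._fit(Xt, yt, "improved", "improved_vs_nonimproved", seed)
            )
        if "stage2" in loocv_stages:
            loocv2 = loocv(
                X[hm], y2, lambda Xt, yt: self._fit(Xt, yt, LABEL_HIGH, "high_vs_medium", seed)
            )
        return CascadeResults(
            model=self,
            labels=pd.Series(labels, index=self.triples, name="label"),
            stage1=stage1,
            stage2=stage2,
            loocv_stage1=loocv1,
            loocv_stage2=loocv2,
            seed=seed,
        )

    def _fit(self, X, y, positive, contrast, seed) -> DiscriminationModel:
        return fit_lasso_discriminator(
            X,
            y,
            positive_label=positive,
            contrast=contrast,
            lambda_policy=self.lambda_policy,
            family=self.family,
            seed=seed,
        )


@dataclass(frozen=True)
class CascadeResults:
    """Fitted cascade: stratification, discriminators, validation, ranking."""

    model: ThermostabilityCascade
    labels: pd.Series
    stage1: DiscriminationModel
    stage2: DiscriminationModel
    loocv_stage1: LoocvReport | None
    loocv_stage2: LoocvReport | None
    seed: int

    @property
    def label_counts(self) -> dict[str, int]:
        vc = self.labels.value_counts()
        return {k: int(vc.get(k, 0)) for k in (LABEL_HIGH, LABEL_MEDIUM, LABEL_LOW)}

    # ------------------------------------------------------------------ #
    def rank_candidates(self, observed: Iterable[str] | None = None) -> CandidateRanking:
        """Enumerate unobserved triples, screen with stage 1, rank with stage 2."""
        obs = set(self.model.triples) if observed is None else set(observed)
        candidates = enumerate_candidate_triples(obs)
        feats = encode_library(candidates, self.model.descriptor_table).to_numpy(float)
        kept, p1 = screen_stage1(self.stage1, candidates, feats)
        idx = {c: i for i, c in enumerate(candidates)}
        kept_idx = [idx[c] for c in kept]
        ranking = rank_stage2(
            self.stage2, kept, feats[kept_idx], stage1_p=p1[kept_idx]
        )
        return ranking

    def select(
        self, ranking: CandidateRanking, n_high: int = 20, n_medium: int = 20
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        return select_top_candidates(ranking, n_high, n_medium)

    def weight_table(self, positions: Sequence[str] = ("pos1", "pos2", "pos3")) -> pd.DataFrame:
        """Stage-2 (high vs medium) weights as descriptors x positions."""
        return extract_weight_table(
            self.stage2, self.model.descriptor_table.descriptor_ids, positions
        )

    # ------------------------------------------------------------------ #
    def summary(self) -> str:
        lines = [
            "Thermostability discrimination cascade",
            "=" * 54,
            f"n mutants:            {len(self.labels)}",
            "label counts:         "
            + ", ".join(f"{k}={v}" for k, v in self.label_counts.items()),
            f"lambda policy:        {self.model.lambda_policy} (family={self.model.family})",
            f"seed:                 {self.seed}",
            "-" * 54,
        ]
        for name, m, lo in (
            ("stage 1 (improved vs non-improved)", self.stage1, self.loocv_stage1),
            ("stage 2 (high vs medium)", self.stage2, self.loocv_stage2),
        ):
            nz = int(np.count_nonzero(m.weights))
            lines.append(f"{name}:")
            lines.append(
                f"  lambda = {m.regularization_strength:.4g}, "
                f"nonzero weights = {nz}/{m.n_features}"
            )
            if lo is not None:
                lines.append(f"  LOOCV accuracy = {lo.accuracy:.3f} (n={lo.n})")
        top = (
            self.weight_table()
            .abs()
            .sum(axis=1)
            .sort_values(ascending=False)
            .head(3)
            .index.tolist()
        )
        lines.append("-" * 54)
        lines.append("largest stage-2 descriptors: " + ", ".join(top))
        return "\n".join(lines)
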