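"""Two-class Fisher Discriminant Analysis with leave-one-out scoring.

The projection direction maximizes the ratio of between-cluster to
within-cluster scatter,

    J(w) = (w' S_B w) / (w' S_W w),

with S_B = sum_i n_i (m_i - m)(m_i - m)' and
S_W = sum_i n_i sum_{j in i} (x_j - m_i)(x_j - m_i)'.  For two classes the
maximizer is colinear with S_W^+ (m_1 - m_2); the general eigen-solution is
kept for cross-checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import linalg

from .data_io import Dataset, Sample

_PINV_RCOND = 1e-10


class FitError(ValueError):
    """Raised when a discriminant model cannot be fitted."""


@dataclass(frozen=True)
class Standardizer:
    """Per-variable affine transform x -> (x - center) / scale."""

    center: np.ndarray
    scale: np.ndarray

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale

    @classmethod
    def fit(cls, X: np.ndarray, *, enabled: bool = True) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if not enabled:
            return cls(np.zeros(X.shape[1]), np.ones(X.shape[1]))
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(center, scale)


@dataclass(frozen=True)
class FDAFit:
    """Scatter matrices and criterion diagnostics of a fitted discriminant."""

    S_B: np.ndarray
    S_W: np.ndarray
    J: float
    eigvals: np.ndarray


@dataclass(frozen=True)
class DiscriminantModel:
    """A fitted two-class discriminant: standardizer, unit direction, orientation."""

    variables: tuple[str, ...]
    standardizer: Standardizer
    w: np.ndarray
    classes: tuple[str, str]  # (positive, negative); positive has higher mean score
    class_score_means: dict[str, float]
    fit: FDAFit

    def to_json(self) -> str:
        return json.dumps(
            {
                "variables": list(self.variables),
                "center": self.standardizer.center.tolist(),
                "scale": self.standardizer.scale.tolist(),
                "w": self.w.tolist(),
                "classes": list(self.classes),
                "class_score_means": self.class_score_means,
                "J": self.fit.J,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DiscriminantModel":
        d = json.loads(text)
        std = Standardizer(np.asarray(d["center"]), np.asarray(d["scale"]))
        w = np.asarray(d["w"])
        p = len(w)
        return cls(
            variables=tuple(d["variables"]),
            standardizer=std,
            w=w,
            classes=tuple(d["classes"]),
            class_score_means=dict(d["class_score_means"]),
            fit=FDAFit(np.zeros((p, p)), np.zeros((p, p)), d["J"], np.zeros(p)),
        )


@dataclass
class CVScores:
    """Per-sample leave-one-out scores; one score per input sample."""

    ids: list[str]
    cohorts: list[str]
    scores: np.ndarray
    fold_count: int

    def by_cohort(self, cohort: str) -> np.ndarray:
        mask = np.array([c == cohort for c in self.cohorts])
        return self.scores[mask]


def scatter_matrices(
    X: np.ndarray, labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Between- and within-cluster scatter, each class weighted by its size."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    grand = X.mean(axis=0)
    p = X.shape[1]
    S_B = np.zeros((p, p))
    S_W = np.zeros((p, p))
    for cls in np.unique(labels):
        Xi = X[labels == cls]
        ni = Xi.shape[0]
        d = (Xi.mean(axis=0) - grand)[:, None]
        S_B += ni * (d @ d.T)
        C = Xi - Xi.mean(axis=0)
        S_W += ni * (C.T @ C)
    return S_B, S_W


def criterion(w: np.ndarray, S_B: np.ndarray, S_W: np.ndarray) -> float:
    """J(w) = (w'S_B w)/(w'S_W w)."""
    w = np.asarray(w, dtype=float)
    denom = float(w @ S_W @ w)
    if denom == 0:
        return np.inf
    return float(w @ S_B @ w) / denom


def _fit_arrays(
    X: np.ndarray,
    labels: Sequence[str],
    classes: tuple[str, str],
    variables: tuple[str, ...],
    *,
    standardize: bool = True,
    diagnostics: bool = True,
) -> DiscriminantModel:
    labels = np.asarray(labels)
    pos, neg = classes
    for c in classes:
        if int(np.sum(labels == c)) < 2:
            raise FitError(f"class {c!r} has fewer than 2 samples")
    std = Standardizer.fit(X, enabled=standardize)
    Z = std(X)
    S_B, S_W = scatter_matrices(Z, labels)
    if not (np.any(S_W) or np.any(S_B)):
        raise FitError("degenerate scatter")

    m1 = Z[labels == pos].mean(axis=0)
    m2 = Z[labels == neg].mean(axis=0)
    SW_pinv = linalg.pinvh(S_W, rtol=_PINV_RCOND)
    w = SW_pinv @ (m1 - m2)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise FitError("degenerate scatter")
    w = w / norm

    if diagnostics:
        # generalized eigenvalues of S_W^+ S_B, for cross-checks and k>2 use
        eigvals = np.sort(np.real(linalg.eigvals(SW_pinv @ S_B)))[::-1]
    else:
        eigvals = np.empty(0)

    s1, s2 = float(w @ m1), float(w @ m2)
    if s1 < s2:
        w = -w
        s1, s2 = s2, s1
        s1, s2 = float(w @ m1), float(w @ m2)
    return DiscriminantModel(
        variables=variables,
        standardizer=std,
        w=w,
        classes=(pos, neg),
        class_score_means={pos: float(w @ m1), neg: float(w @ m2)},
        fit=FDAFit(S_B=S_B, S_W=S_W, J=criterion(w, S_B, S_W), eigvals=eigvals),
    )


def fit_fda(
    ds: Dataset,
    variables: Iterable[str],
    classes: tuple[str, str] = ("ASD", "NEU"),
    *,
    standardize: bool = True,
) -> DiscriminantModel:
    """Fit the two-class discriminant on the named cohorts and variables.

    The sign of the direction is fixed so that the first class in ``classes``
    has the higher mean projected score.
    """
    variables = tuple(variables)
    if not variables:
        raise FitError("need at least one variable")
    sub = ds.subset_cohorts(classes)
    X = sub.matrix(variables)
    labels = [s.cohort for s in sub.samples]
    return _fit_arrays(X, labels, classes, variables, standardize=standardize)


def project_scores(m: DiscriminantModel, samples: Iterable[Sample] | Dataset) -> np.ndarray:
    """Scalar discriminant score w' z for each sample."""
    if isinstance(samples, Dataset):
        X = samples.matrix(m.variables)
    else:
        samples = list(samples)
        if not samples:
            return np.empty(0)
        ds_like = [s.values for s in samples]
        X = np.stack(ds_like)
        # caller guarantees panel alignment when passing raw samples
        if X.shape[1] != len(m.variables):
            raise FitError(
                f"sample dimension {X.shape[1]} != model dimension {len(m.variables)}"
            )
    return m.standardizer(X) @ m.w


def loo_scores(
    ds: Dataset,
    variables: Iterable[str],
    classes: tuple[str, str] = ("ASD", "NEU"),
    *,
    standardize: bool = True,
) -> CVScores:
    """Leave-one-out cross-validated scores over the two named cohorts.

    Each sample is scored by a model fitted (standardizer included) on all
    other samples of the two cohorts.  Deterministic; independent of row
    order.
    """
    variables = tuple(variables)
    sub = ds.subset_cohorts(classes)
    for c in classes:
        if sub.cohort_counts().get(c, 0) < 3:
            raise FitError(f"class {c!r} needs >= 3 samples for leave-one-out")
    X = sub.matrix(variables)
    labels = np.asarray([s.cohort for s in sub.samples])
    ids = [s.id for s in sub.samples]
    n, p = X.shape
    pos, neg = classes

    # per-fold refits via moment downdates: totals minus the held-out row
    tot_sum = X.sum(axis=0)
    tot_sq = (X**2).sum(axis=0)
    cls_stats = {}
    for c in classes:
        Xc = X[labels == c]
        cls_stats[c] = (Xc.shape[0], Xc.sum(axis=0), Xc.T @ Xc)

    scores = np.empty(n)
    for j in range(n):
        xj = X[j]
        cj = labels[j]
        if standardize:
            center = (tot_sum - xj) / (n - 1)
            var = (tot_sq - xj**2 - (n - 1) * center**2) / (n - 2)
            scale = np.sqrt(np.maximum(var, 0.0))
            scale = np.where(scale > 0, scale, 1.0)
        else:
            center = np.zeros(p)
            scale = np.ones(p)
        D = 1.0 / scale

        S_W = np.zeros((p, p))
        means = {}
        for c in classes:
            nc, sc, gc = cls_stats[c]
            if c == cj:
                nc, sc, gc = nc - 1, sc - xj, gc - np.outer(xj, xj)
            if nc < 1:
                raise FitError(f"fold {j}: class {c!r} empty after hold-out")
            mc = sc / nc
            means[c] = mc
            S_W += nc * (gc - nc * np.outer(mc, mc))
        S_W *= np.outer(D, D)
        diff = D * (means[pos] - means[neg])
        w = np.linalg.pinv(S_W, rcond=_PINV_RCOND, hermitian=True) @ diff
        norm = np.linalg.norm(w)
        if norm == 0:
            raise FitError(f"fold {j} (held-out sample {ids[j]!r}): degenerate scatter")
        w = w / norm
        if w @ diff < 0:
            w = -w
        scores[j] = w @ ((xj - center) * D)
    return CVScores(ids=ids, cohorts=list(labels), scores=scores, fold_count=n)


def project_external(
    m: DiscriminantModel, ds: Dataset, cohort: str
) -> list[tuple[str, float]]:
    """Score every sample of ``cohort`` with a frozen model (no refit)."""
    samples = [s for s in ds.samples if s.cohort == cohort]
    if not samples:
        raise FitError(f"cohort {cohort!r} absent from dataset")
    X = np.stack([s.values[[ds.panel.index(v) for v in m.variables]] for s in samples])
    scores = m.standardizer(X) @ m.w
    return [(s.id, float(sc)) for s, sc in zip(samples, scores)]


def save_model(m: DiscriminantModel, path: str | Path) -> None:
    Path(path).write_text(m.to_json())


def load_model(path: str | Path) -> DiscriminantModel:
    return DiscriminantModel.from_json(Path(path).read_text())
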