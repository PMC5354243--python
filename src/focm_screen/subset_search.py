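"""Metabolite subset selection by cross-validated C-statistic.

Exhaustive evaluation of all combinations up to a size cap, greedy
extension beyond it, and a sibling-separability criterion for augmenting a
chosen panel.  Every combination is scored by the same pipeline:
leave-one-out FDA scores -> per-cohort LSCV KDE -> PDF-based ROC area.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from joblib import Parallel, delayed

from .data_io import Dataset
from .density import fit_distribution
from .fda import fit_fda, loo_scores, project_external, CVScores
from .roc_classify import roc_c_statistic


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class ComboScore:
    variables: tuple[str, ...]
    c_statistic: float
    c_statistic_sib: float | None = None


@dataclass
class SearchResult:
    best_by_size: dict[int, ComboScore]
    evaluated_count: int
    search_mode: str  # "exhaustive" | "greedy"


def _canonical(ds: Dataset, variables: Iterable[str]) -> tuple[str, ...]:
    order = {v: i for i, v in enumerate(ds.panel.names)}
    return tuple(sorted(variables, key=order.__getitem__))


def _cv_c_statistic(
    ds: Dataset, variables: tuple[str, ...], classes: tuple[str, str]
) -> float:
    cv = loo_scores(ds, variables, classes)
    pdf_pos = fit_distribution(cv.by_cohort(classes[0]))
    pdf_neg = fit_distribution(cv.by_cohort(classes[1]))
    return roc_c_statistic(pdf_pos, pdf_neg).c_statistic


def sib_projection_c_statistic(
    ds: Dataset,
    variables: tuple[str, ...],
    classes: tuple[str, str] = ("ASD", "NEU"),
    sib_cohort: str = "SIB",
) -> float:
    """ASD-vs-SIB separability: LOO ASD scores against frozen-model SIB scores."""
    cv = loo_scores(ds, variables, classes)
    model = fit_fda(ds, variables, classes)
    sib_scores = [s for _, s in project_external(model, ds, sib_cohort)]
    pdf_pos = fit_distribution(cv.by_cohort(classes[0]))
    pdf_sib = fit_distribution(np.asarray(sib_scores))
    return roc_c_statistic(pdf_pos, pdf_sib).c_statistic


def combo_c_statistic(
    ds: Dataset,
    variables: Iterable[str],
    classes: tuple[str, str] = ("ASD", "NEU"),
    *,
    with_sib: bool = False,
) -> ComboScore:
    """Score one variable combination through the full CV pipeline."""
    variables = _canonical(ds, variables)
    if not variables:
        raise SearchError("empty variable combination")
    try:
        c = _cv_c_statistic(ds, variables, classes)
        c_sib = (
            sib_projection_c_statistic(ds, variables, classes) if with_sib else None
        )
    except Exception as e:
        raise SearchError(f"combination {variables}: {e}") from e
    return ComboScore(variables=variables, c_statistic=c, c_statistic_sib=c_sib)


def _better(a: ComboScore, b: ComboScore | None) -> bool:
    """True if a beats b under (C desc, fewer vars, lexicographic) ordering."""
    if b is None:
        return True
    if a.c_statistic != b.c_statistic:
        return a.c_statistic > b.c_statistic
    if len(a.variables) != len(b.variables):
        return len(a.variables) < len(b.variables)
    return a.variables < b.variables


def exhaustive_search(
    ds: Dataset,
    k_max: int = 6,
    classes: tuple[str, str] = ("ASD", "NEU"),
    *,
    variables: Sequence[str] | None = None,
    n_jobs: int = 1,
) -> SearchResult:
    """Evaluate every combination of size 1..k_max; keep the best per size.

    Results are identical for any worker count: each size is reduced in the
    deterministic enumeration order of :func:`itertools.combinations`.
    """
    pool = tuple(variables) if variables is not None else ds.panel.names
    if k_max > len(pool):
        raise SearchError("k_max exceeds the number of candidate variables")
    best_by_size: dict[int, ComboScore] = {}
    evaluated = 0
    for k in range(1, k_max + 1):
        combos = [
            _canonical(ds, c) for c in itertools.combinations(pool, k)
        ]
        evaluated += len(combos)
        if n_jobs == 1:
            cs = [_cv_c_statistic(ds, c, classes) for c in combos]
        else:
            cs = Parallel(n_jobs=n_jobs)(
                delayed(_cv_c_statistic)(ds, c, classes) for c in combos
            )
        best: ComboScore | None = None
        for combo, c in zip(combos, cs):
            cand = ComboScore(variables=combo, c_statistic=c)
            if _better(cand, best):
                best = cand
        best_by_size[k] = best  # type: ignore[assignment]
    assert evaluated == sum(math.comb(len(pool), k) for k in range(1, k_max + 1))
    return SearchResult(
        best_by_size=best_by_size, evaluated_count=evaluated, search_mode="exhaustive"
    )


def greedy_extend(
    ds: Dataset,
    base: ComboScore,
    k_extra: int,
    criterion: str = "classification",
    classes: tuple[str, str] = ("ASD", "NEU"),
    *,
    variables: Sequence[str] | None = None,
    max_classification_drop: float = 0.002,
) -> list[ComboScore]:
    """Extend a combination one variable at a time, maximizing a criterion.

    ``criterion="classification"`` maximizes the ASD-vs-NEU C-statistic;
    ``criterion="sib_separability"`` maximizes the ASD-vs-SIB C-statistic
    subject to not lowering the ASD-vs-NEU C by more than
    ``max_classification_drop``.  Ties break by canonical variable order.
    Returns the trajectory, starting with ``base``.
    """
    if criterion not in ("classification", "sib_separability"):
        raise SearchError(f"unknown criterion {criterion!r}")
    pool = tuple(variables) if variables is not None else ds.panel.names
    if not base.variables:
        raise SearchError("base combination is empty")
    remaining = [v for v in pool if v not in base.variables]
    if k_extra > len(remaining):
        raise SearchError("k_extra exceeds the remaining variables")

    current = base
    trajectory = [base]
    base_c = base.c_statistic
    for _ in range(k_extra):
        best_var: str | None = None
        best_key: tuple | None = None
        best_score: ComboScore | None = None
        for v in remaining:
            cand_vars = _canonical(ds, current.variables + (v,))
            c = _cv_c_statistic(ds, cand_vars, classes)
            if criterion == "classification":
                key = (c,)
                score = ComboScore(cand_vars, c)
            else:
                if c < base_c - max_classification_drop:
                    continue
                c_sib = sib_projection_c_statistic(ds, cand_vars, classes)
                key = (c_sib,)
                score = ComboScore(cand_vars, c, c_statistic_sib=c_sib)
            if best_key is None or key > best_key:
                best_key, best_var, best_score = key, v, score
        if best_var is None:
            raise SearchError(
                "no admissible variable under the sib_separability constraint"
            )
        remaining.remove(best_var)
        current = best_score  # type: ignore[assignment]
        trajectory.append(current)
    return trajectory
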