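"""Reading, validating and writing participant metabolite tables."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panel import COHORTS, MetabolitePanel, normalize_name, resolve_variable

_COHORT_ALIASES = {
    "asd": "ASD",
    "aut": "ASD",
    "autism": "ASD",
    "case": "ASD",
    "sib": "SIB",
    "sibling": "SIB",
    "neu": "NEU",
    "neurotypical": "NEU",
    "control": "NEU",
    "ctrl": "NEU",
}


class DataError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass(frozen=True)
class Sample:
    """One participant: id, cohort, panel-aligned values, optional Vineland."""

    id: str
    cohort: str
    values: np.ndarray
    vineland: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )
        if self.cohort not in COHORTS:
            raise DataError(f"unknown cohort label {self.cohort!r}")
        if not np.all(np.isfinite(self.values)):
            raise DataError(f"sample {self.id!r} has non-finite values")


@dataclass
class Dataset:
    """A panel plus aligned samples; the table every pipeline stage consumes."""

    panel: MetabolitePanel
    samples: list[Sample]
    provenance: dict = field(default_factory=lambda: {"source": "unknown"})

    def __len__(self) -> int:
        return len(self.samples)

    def cohort_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.samples:
            counts[s.cohort] = counts.get(s.cohort, 0) + 1
        return counts

    def subset_cohorts(self, cohorts: Iterable[str]) -> "Dataset":
        wanted = set(cohorts)
        return Dataset(
            panel=self.panel,
            samples=[s for s in self.samples if s.cohort in wanted],
            provenance=dict(self.provenance),
        )

    def matrix(self, variables: Iterable[str] | None = None) -> np.ndarray:
        """(n_samples, n_variables) array for the named variables."""
        names = tuple(variables) if variables is not None else self.panel.names
        idx = [self.panel.index(v) for v in names]
        if not self.samples:
            return np.empty((0, len(idx)))
        return np.stack([s.values[idx] for s in self.samples])

    def cohort_matrix(self, cohort: str, variables: Iterable[str] | None = None) -> np.ndarray:
        names = tuple(variables) if variables is not None else self.panel.names
        idx = [self.panel.index(v) for v in names]
        rows = [s.values[idx] for s in self.samples if s.cohort == cohort]
        if not rows:
            return np.empty((0, len(idx)))
        return np.stack(rows)

    def mean_vector(self) -> np.ndarray:
        return self.matrix().mean(axis=0)

    def cohort_mean(self, cohort: str) -> np.ndarray:
        return self.cohort_matrix(cohort).mean(axis=0)

    def vineland_subset(self) -> "Dataset":
        """ASD samples carrying a response score."""
        return Dataset(
            panel=self.panel,
            samples=[
                s for s in self.samples if s.cohort == "ASD" and s.vineland is not None
            ],
            provenance=dict(self.provenance),
        )


@dataclass(frozen=True)
class Inconsistency:
    sample_id: str
    variable: str
    kind: str  # "ratio_mismatch" | "nonpositive"
    stored: float
    expected: float | None = None


@dataclass
class ValidationReport:
    records: list[Inconsistency] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "sample_id": r.sample_id,
                    "variable": r.variable,
                    "kind": r.kind,
                    "stored": r.stored,
                    "expected": r.expected,
                }
                for r in self.records
            ],
            indent=2,
        )

    def to_text(self) -> str:
        if not self.records:
            return "validation: no inconsistencies\n"
        lines = [f"validation: {len(self.records)} inconsistencies"]
        for r in self.records:
            lines.append(
                f"  sample={r.sample_id} variable={r.variable!r} {r.kind} "
                f"stored={r.stored:g}"
                + (f" expected={r.expected:g}" if r.expected is not None else "")
            )
        return "\n".join(lines) + "\n"


def _normalize_cohort(label: str, cohort_map: Mapping[str, str] | None = None) -> str:
    key = normalize_name(str(label))
    if cohort_map:
        mapped = {normalize_name(k): v for k, v in cohort_map.items()}
        if key in mapped:
            return mapped[key]
    if key in _COHORT_ALIASES:
        return _COHORT_ALIASES[key]
    raise DataError(f"unknown cohort label {label!r}")


def load_dataset(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    panel: MetabolitePanel | None = None,
    cohort_column: str | None = None,
    id_column: str | None = None,
    vineland_column: str | None = None,
    cohort_map: Mapping[str, str] | None = None,
    missing_policy: str = "error",
) -> Dataset:
    """Read a delimited participant table into a :class:`Dataset`.

    Parameters
    ----------
    path:
        CSV file, one row per participant, header row required.
    schema:
        Optional alias map raw-header -> canonical variable name, augmenting
        the built-in normalization.
    missing_policy:
        ``"error"`` (default) raises on any missing value; ``"drop"``
        silently drops affected rows (never imputes).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    panel = panel or MetabolitePanel.default()

    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise DataError("no samples")

    extra = dict(schema) if schema else {}
    colmap: dict[str, str] = {}  # canonical -> raw header
    cohort_col = cohort_column
    vineland_col = vineland_column
    id_col = id_column
    for raw in df.columns:
        canon = resolve_variable(raw, extra)
        if canon is not None and canon in panel.names:
            colmap[canon] = raw
            continue
        key = normalize_name(raw)
        if cohort_col is None and key in {"cohort", "group", "class", "diagnosis", "status"}:
            cohort_col = raw
        elif vineland_col is None and key.startswith("vineland"):
            vineland_col = raw
        elif id_col is None and key in {"id", "sampleid", "participant", "participantid", "subject", "subjectid"}:
            id_col = raw

    missing = [v for v in panel.names if v not in colmap]
    if missing:
        raise DataError(f"missing panel column(s): {missing}")
    if cohort_col is None:
        raise DataError("no cohort column found")

    samples: list[Sample] = []
    for i, row in df.iterrows():
        sid = str(row[id_col]) if id_col is not None else str(i)
        vals = np.empty(len(panel.names))
        bad = None
        for j, v in enumerate(panel.names):
            cell = row[colmap[v]]
            try:
                x = float(cell)
            except (TypeError, ValueError):
                raise DataError(
                    f"non-numeric value {cell!r} at row {i}, column {colmap[v]!r}"
                )
            if not np.isfinite(x):
                bad = v
                break
            vals[j] = x
        if bad is not None:
            if missing_policy == "drop":
                continue
            raise DataError(f"missing value at row {i}, column {bad!r}")
        cohort = _normalize_cohort(row[cohort_col], cohort_map)
        vineland = None
        if vineland_col is not None:
            raw_v = row[vineland_col]
            if raw_v is not None and not pd.isna(raw_v):
                vineland = float(raw_v)
        samples.append(Sample(id=sid, cohort=cohort, values=vals, vineland=vineland))

    if not samples:
        raise DataError("no samples")
    return Dataset(
        panel=panel,
        samples=samples,
        provenance={"source": "real", "path": str(path)},
    )


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a Dataset back to CSV in the same layout :func:`load_dataset` reads."""
    path = Path(path)
    cols: dict[str, list] = {"id": [], "cohort": []}
    for v in ds.panel.names:
        cols[v] = []
    cols["Vineland"] = []
    for s in ds.samples:
        cols["id"].append(s.id)
        cols["cohort"].append(s.cohort)
        for j, v in enumerate(ds.panel.names):
            cols[v].append(repr(float(s.values[j])))
        cols["Vineland"].append("" if s.vineland is None else repr(float(s.vineland)))
    pd.DataFrame(cols).to_csv(path, index=False)


def validate_panel(ds: Dataset, rel_tol: float = 0.01) -> ValidationReport:
    """Report-only consistency checks: ratio columns vs their components and
    positivity of strictly positive analytes."""
    report = ValidationReport()
    ratios = ds.panel.checkable_ratios()
    ratio_names = set(ratios)
    for s in ds.samples:
        for r, (num, den) in ratios.items():
            stored = s.values[ds.panel.index(r)]
            n_v = s.values[ds.panel.index(num)]
            d_v = s.values[ds.panel.index(den)]
            if d_v == 0:
                continue
            expected = n_v / d_v
            denom = max(abs(expected), 1e-300)
            if abs(stored - expected) / denom > rel_tol:
                report.records.append(
                    Inconsistency(s.id, r, "ratio_mismatch", stored, expected)
                )
        for j, v in enumerate(ds.panel.names):
            if v in ratio_names:
                continue
            if s.values[j] <= 0:
                report.records.append(
                    Inconsistency(s.id, v, "nonpositive", s.values[j])
                )
    return report
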