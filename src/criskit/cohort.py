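"""Cohort data model: subjects, covariate schema, CSV round-trip and descriptives.

A cohort is a set of right-censored competing-risks records.  Each subject
carries a follow-up ``time`` (strictly positive, measured from a common
origin), an integer ``event`` code in ``{0, 1, ..., K}`` where 0 means
censored, and a mapping of raw covariate values.  Categorical covariates are
declared in a :class:`Schema` with an explicit level order and reference
level, and are expanded to reference-coded dummies by :func:`encode`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortError",
    "SchemaError",
    "ValidationError",
    "Covariate",
    "Schema",
    "Cohort",
    "DesignMatrix",
    "read_cohort",
    "write_cohort",
    "encode",
    "describe_cohort",
]


class CohortError(Exception):
    """Base class for cohort construction problems."""


class SchemaError(CohortError):
    """A covariate or column is missing or inconsistently declared."""


class ValidationError(CohortError):
    """Row-level data violates an invariant (non-positive time, bad event code)."""


@dataclass(frozen=True)
class Covariate:
    """Declaration of one covariate.

    ``kind`` is ``"numeric"`` or ``"categorical"``.  Categorical covariates
    list their levels in display order; ``reference`` defaults to the first
    level and must be one of the declared levels.
    """

    name: str
    kind: str = "numeric"
    levels: tuple[str, ...] = ()
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise SchemaError(f"unknown covariate kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise SchemaError(f"categorical covariate {self.name!r} declares no levels")
            ref = self.reference if self.reference is not None else self.levels[0]
            if ref not in self.levels:
                raise SchemaError(
                    f"reference level {ref!r} of {self.name!r} is not a declared level"
                )
            object.__setattr__(self, "reference", ref)
            object.__setattr__(self, "levels", tuple(self.levels))


@dataclass(frozen=True)
class Schema:
    covariates: tuple[Covariate, ...] = ()

    def __getitem__(self, name: str) -> Covariate:
        for cov in self.covariates:
            if cov.name == name:
                return cov
        raise SchemaError(f"unknown covariate {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.covariates)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    @classmethod
    def from_dict(cls, spec: Mapping[str, Any]) -> "Schema":
        """Build a schema from a plain mapping (e.g. parsed YAML/JSON).

        Numeric: ``{"age": "numeric"}``.  Categorical:
        ``{"sex": {"levels": ["female", "male"], "reference": "female"}}``.
        """
        covs = []
        for name, v in spec.items():
            if isinstance(v, str):
                if v != "numeric":
                    raise SchemaError(f"covariate {name!r}: expected 'numeric', got {v!r}")
                covs.append(Covariate(name))
            else:
                covs.append(
                    Covariate(
                        name,
                        kind="categorical",
                        levels=tuple(str(x) for x in v["levels"]),
                        reference=str(v["reference"]) if "reference" in v else None,
                    )
                )
        return cls(tuple(covs))

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for c in self.covariates:
            if c.kind == "numeric":
                out[c.name] = "numeric"
            else:
                out[c.name] = {"levels": list(c.levels), "reference": c.reference}
        return out


@dataclass(frozen=True)
class Subject:
    id: Any
    time: float
    event: int
    covariates: Mapping[str, Any] = field(default_factory=dict)


class Cohort:
    """Ordered collection of subjects with a covariate schema.

    ``n_causes`` (K) is at least the largest event code present; it may be
    declared larger to represent causes with no observed events.
    """

    def __init__(
        self,
        ids: Sequence[Any],
        times: Sequence[float],
        events: Sequence[int],
        covariates: Mapping[str, Sequence[Any]] | None = None,
        n_causes: int | None = None,
        schema: Schema | None = None,
        label: str = "",
    ) -> None:
        self.ids = np.asarray(ids, dtype=object)
        self.times = np.asarray(times, dtype=float)
        self.events = np.asarray(events, dtype=int)
        n = self.times.size
        if not (self.ids.size == n == self.events.size):
            raise ValidationError("ids, times and events must have equal length")
        bad = np.nonzero(~np.isfinite(self.times) | (self.times <= 0))[0]
        if bad.size:
            raise ValidationError(
                "non-positive or non-finite follow-up time for row(s) "
                + ", ".join(str(self.ids[i]) for i in bad[:20])
            )
        if np.any(self.events < 0):
            raise ValidationError("negative event codes are not allowed")
        max_code = int(self.events.max(initial=0))
        if n_causes is None:
            n_causes = max(max_code, 1)
        if max_code > n_causes:
            bad = np.nonzero(self.events > n_causes)[0]
            raise ValidationError(
                f"event code exceeds n_causes={n_causes} for row(s) "
                + ", ".join(str(self.ids[i]) for i in bad[:20])
            )
        self.n_causes = int(n_causes)
        self.covariates = {k: np.asarray(v) for k, v in (covariates or {}).items()}
        for k, v in self.covariates.items():
            if v.size != n:
                raise ValidationError(f"covariate {k!r} has length {v.size}, expected {n}")
        if schema is None:
            schema = Schema(tuple(Covariate(k) for k in self.covariates))
        for name in schema.names:
            if name not in self.covariates:
                raise SchemaError(f"schema covariate {name!r} absent from data")
        self.schema = schema
        self.label = label

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n(self) -> int:
        return len(self)

    def to_frame(self) -> pd.DataFrame:
        d = {"id": self.ids, "time": self.times, "event": self.events}
        d.update({k: v for k, v in self.covariates.items()})
        return pd.DataFrame(d)

    def subset(self, mask) -> "Cohort":
        mask = np.asarray(mask)
        return Cohort(
            self.ids[mask],
            self.times[mask],
            self.events[mask],
            {k: v[mask] for k, v in self.covariates.items()},
            n_causes=self.n_causes,
            schema=self.schema,
            label=self.label,
        )

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.n_causes == other.n_causes
            and self.schema == other.schema
            and np.array_equal(self.ids, other.ids)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.events, other.events)
            and set(self.covariates) == set(other.covariates)
            and all(np.array_equal(self.covariates[k], other.covariates[k]) for k in self.covariates)
        )


def read_cohort(
    path,
    column_map: Mapping[str, str] | None = None,
    n_causes: int | None = None,
    schema: Schema | Mapping[str, Any] | None = None,
) -> Cohort:
    """Read a cohort from CSV.

    The file must be comma-separated with a header row; ``column_map`` maps
    the canonical names ``id``, ``time``, ``event`` to file columns (identity
    by default).  All remaining columns are taken as covariates.  Rows with
    missing time or event are rejected with an error naming them — never
    silently dropped.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cmap = {"id": "id", "time": "time", "event": "event"}
    if column_map:
        cmap.update(column_map)
    for canon, col in cmap.items():
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} (for {canon!r}) missing from {path}")
    missing = df.index[df[cmap["time"]].isna() | df[cmap["event"]].isna()]
    if len(missing):
        raise ValidationError(
            "missing time/event in row(s) " + ", ".join(str(i) for i in missing[:20])
        )
    ev = df[cmap["event"]]
    if not np.array_equal(ev.astype(float), ev.astype(float).round()):
        raise ValidationError("event codes must be integers")
    cov_cols = [c for c in df.columns if c not in set(cmap.values())]
    if isinstance(schema, Mapping):
        schema = Schema.from_dict(schema)
    return Cohort(
        df[cmap["id"]].to_numpy(),
        df[cmap["time"]].to_numpy(dtype=float),
        ev.to_numpy(dtype=int),
        {c: df[c].to_numpy() for c in cov_cols},
        n_causes=n_causes,
        schema=schema,
    )


def write_cohort(cohort: Cohort, path, schema_path=None) -> None:
    """Write a cohort to CSV (and optionally its schema to JSON)."""
    cohort.to_frame().to_csv(path, index=False)
    if schema_path is not None:
        with open(schema_path, "w") as fh:
            json.dump({"n_causes": cohort.n_causes, "schema": cohort.schema.to_dict()}, fh, indent=1)


@dataclass(frozen=True)
class DesignMatrix:
    """Numeric design matrix with reference-coded categorical dummies."""

    matrix: np.ndarray
    column_names: tuple[str, ...]
    encoding_map: Mapping[str, tuple[str, ...]]

    @property
    def n_columns(self) -> int:
        return int(self.matrix.shape[1])


def _dummy_name(cov: str, level: str) -> str:
    safe = str(level)
    for ch in " <>-=/":
        safe = safe.replace(ch, "_")
    return f"{cov}_{safe}" if safe else cov


def encode(cohort: Cohort, covariate_names: Iterable[str]) -> DesignMatrix:
    """Expand the named covariates into a reference-coded design matrix.

    A categorical covariate with L levels yields L-1 dummy columns (the
    reference level is dropped); numeric covariates pass through as a single
    column.  Column order follows declaration order, then level order, so the
    encoding is deterministic.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    emap: dict[str, tuple[str, ...]] = {}
    for name in covariate_names:
        if name not in cohort.covariates:
            raise SchemaError(f"unknown covariate {name!r}")
        cov = cohort.schema[name] if name in cohort.schema else Covariate(name)
        raw = cohort.covariates[name]
        if cov.kind == "numeric":
            cols.append(np.asarray(raw, dtype=float))
            names.append(name)
            emap[name] = (name,)
        else:
            observed = set(str(x) for x in raw)
            unknown = observed - set(cov.levels)
            if unknown:
                raise ValidationError(f"covariate {name!r} has undeclared level(s) {sorted(unknown)}")
            dnames = []
            for level in cov.levels:
                if level == cov.reference:
                    continue
                col = (raw.astype(str) == level).astype(float)
                if not col.any() and len(observed) == 1:
                    warnings.warn(
                        f"covariate {name!r}: level {level!r} unobserved; "
                        "column is all zeros (non-identifiable)",
                        UserWarning,
                        stacklevel=2,
                    )
                dn = _dummy_name(name, level)
                cols.append(col)
                names.append(dn)
                dnames.append(dn)
            emap[name] = tuple(dnames)
    mat = np.column_stack(cols) if cols else np.empty((len(cohort), 0))
    return DesignMatrix(mat, tuple(names), emap)


def encode_profile(
    schema: Schema, covariate_names: Sequence[str], profile: Mapping[str, Any]
) -> np.ndarray:
    """Encode a single covariate profile into a design row.

    Uses the same reference-level dummy coding and column order as
    :func:`encode`, so the result lines up with a fitted model's
    coefficients.  Every named covariate must be present in ``profile``.
    """
    vals: list[float] = []
    for name in covariate_names:
        if name not in profile:
            raise SchemaError(f"profile is missing covariate {name!r}")
        cov = schema[name] if name in schema else Covariate(name)
        raw = profile[name]
        if cov.kind == "numeric":
            vals.append(float(raw))
        else:
            if str(raw) not in cov.levels:
                raise ValidationError(
                    f"profile value {raw!r} is not a level of {name!r} {cov.levels}"
                )
            for level in cov.levels:
                if level == cov.reference:
                    continue
                vals.append(1.0 if str(raw) == level else 0.0)
    return np.asarray(vals)


def describe_cohort(cohort: Cohort) -> pd.DataFrame:
    """Tidy (measure, value) descriptives: n, per-cause event counts and
    percentages, censoring count, median follow-up, and categorical covariate
    level counts/percentages."""
    if len(cohort) == 0:
        raise ValidationError("cannot describe an empty cohort")
    n = len(cohort)
    rows: list[tuple[str, float]] = [("n", float(n))]
    for k in range(1, cohort.n_causes + 1):
        cnt = int(np.sum(cohort.events == k))
        rows.append((f"events_cause{k}", float(cnt)))
        rows.append((f"pct_cause{k}", 100.0 * cnt / n))
    cens = int(np.sum(cohort.events == 0))
    rows.append(("censored", float(cens)))
    rows.append(("pct_censored", 100.0 * cens / n))
    rows.append(("median_followup", float(np.median(cohort.times))))
    for cov in cohort.schema.covariates:
        raw = cohort.covariates[cov.name]
        if cov.kind == "categorical":
            for level in cov.levels:
                cnt = int(np.sum(raw.astype(str) == level))
                rows.append((f"{cov.name}={level}_count", float(cnt)))
                rows.append((f"pct_{cov.name}={level}", 100.0 * cnt / n))
        else:
            vals = raw.astype(float)
            uniq = np.unique(vals[~np.isnan(vals)])
            if uniq.size <= 2 and set(uniq) <= {0.0, 1.0}:
                cnt = int(np.nansum(vals))
                rows.append((f"{cov.name}_count", float(cnt)))
                rows.append((f"pct_{cov.name}", 100.0 * cnt / n))
            else:
                rows.append((f"mean_{cov.name}", float(np.nanmean(vals))))
                rows.append((f"sd_{cov.name}", float(np.nanstd(vals, ddof=1))))
    return pd.DataFrame(rows, columns=["measure", "value"])
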