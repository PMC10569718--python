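"""Core survival data containers, validation, standardization and delimited I/O.

The package works on collections of right-censored survival tables — one per
disease ("task") — that share a single feature registry.  Each table records,
per subject, a follow-up time in years, a binary event indicator (1 =
uncensored, the disease occurred; 0 = censored) and the shared feature columns.
Downstream modules (Cox partial likelihood, the multitask solver, the risk
layer) all consume the types defined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureRegistry",
    "SurvivalTask",
    "MultiTaskDataset",
    "RiskSetIndex",
    "Standardization",
    "load_tasks",
    "write_tasks",
    "standardize",
    "apply_standardization",
    "build_risk_sets",
]

DAYS_PER_YEAR = 365.25

FeatureKind = Literal["continuous", "binary"]


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered shared feature schema: names plus per-feature kind.

    Binary features are passed through standardization untouched; continuous
    features are centered and scaled.
    """

    names: tuple[str, ...]
    kinds: tuple[FeatureKind, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.kinds):
            raise ValueError("names and kinds must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names in registry")
        for k in self.kinds:
            if k not in ("continuous", "binary"):
                raise ValueError(f"unknown feature kind {k!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "FeatureRegistry":
        return cls(tuple(mapping.keys()), tuple(mapping.values()))  # type: ignore[arg-type]

    @property
    def n_features(self) -> int:
        return len(self.names)

    @property
    def continuous_mask(self) -> np.ndarray:
        return np.array([k == "continuous" for k in self.kinds], dtype=bool)


@dataclass
class SurvivalTask:
    """One disease's right-censored design matrix.

    Attributes
    ----------
    task_name : str
        Disease / task label.
    features : ndarray of shape (n_subjects, n_features)
        Covariate matrix, column order fixed by the shared registry.
    time : ndarray of shape (n_subjects,)
        Follow-up time in years; strictly positive.
    event : ndarray of shape (n_subjects,)
        1 for an observed (uncensored) event, 0 for censored.
    subject_ids : ndarray of shape (n_subjects,), optional
        Stable identifiers carried through reports.
    """

    task_name: str
    features: np.ndarray
    time: np.ndarray
    event: np.ndarray
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.event = np.asarray(self.event).ravel()
        n = self.features.shape[0]
        if self.time.shape[0] != n or self.event.shape[0] != n:
            raise ValueError("time/event length must match number of feature rows")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError(
                f"task {self.task_name!r}: times must be strictly positive and finite"
            )
        ev = np.asarray(self.event, dtype=float)
        if not np.all(np.isin(ev, (0.0, 1.0))):
            bad = np.unique(ev[~np.isin(ev, (0.0, 1.0))])
            raise ValueError(
                f"task {self.task_name!r}: event indicator must be 0 or 1, found {bad}"
            )
        self.event = ev.astype(np.int8)
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"task {self.task_name!r}: features contain non-finite values")
        if self.subject_ids is None:
            self.subject_ids = np.arange(n)
        else:
            self.subject_ids = np.asarray(self.subject_ids)
            if self.subject_ids.shape[0] != n:
                raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass(frozen=True)
class Standardization:
    """Stored center/scale of the continuous features so the identical affine
    transform can be applied to new subjects."""

    center: np.ndarray  # length P, zeros for binary features
    scale: np.ndarray  # length P, ones for binary / zero-variance features
    scope: Literal["pooled", "per_task"] = "pooled"
    per_task: tuple[tuple[np.ndarray, np.ndarray], ...] | None = None


@dataclass
class MultiTaskDataset:
    """K survival tasks aligned on one shared feature registry."""

    tasks: list[SurvivalTask]
    registry: FeatureRegistry
    standardization: Standardization | None = None

    def __post_init__(self) -> None:
        if len(self.tasks) < 1:
            raise ValueError("need at least one task")
        names = [t.task_name for t in self.tasks]
        if len(set(names)) != len(names):
            raise ValueError("task names must be unique")
        p = self.registry.n_features
        for t in self.tasks:
            if t.n_features != p:
                raise ValueError(
                    f"task {t.task_name!r} has {t.n_features} features, registry has {p}"
                )

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    @property
    def n_features(self) -> int:
        return self.registry.n_features

    @property
    def task_names(self) -> list[str]:
        return [t.task_name for t in self.tasks]

    @property
    def feature_names(self) -> list[str]:
        return list(self.registry.names)

    def task(self, name: str) -> SurvivalTask:
        for t in self.tasks:
            if t.task_name == name:
                return t
        raise KeyError(name)

    def subset(self, masks: Sequence[np.ndarray]) -> "MultiTaskDataset":
        """Row-subset every task (boolean or index arrays, one per task)."""
        new = [
            SurvivalTask(
                t.task_name,
                t.features[m],
                t.time[m],
                t.event[m],
                t.subject_ids[m] if t.subject_ids is not None else None,
            )
            for t, m in zip(self.tasks, masks)
        ]
        return MultiTaskDataset(new, self.registry, self.standardization)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_REQUIRED = ("id", "time", "event")


def load_tasks(
    paths: Mapping[str, str | Path],
    registry: FeatureRegistry,
    *,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
    time_unit: Literal["years", "days"] = "years",
) -> MultiTaskDataset:
    """Read one delimited file per task and align them on the registry.

    Parameters
    ----------
    paths : mapping task name -> file path
    registry : shared feature schema; every file must contain these columns.
    column_map : optional rename of the required columns, e.g.
        ``{"time": "follow_up"}`` when the file calls the time column
        ``follow_up``.
    time_unit : ``"days"`` converts to years with 365.25 d/yr.

    Rows with missing required values are dropped with a per-row report
    (a ``UserWarning`` listing file and row numbers).
    """
    colmap = {c: c for c in _REQUIRED}
    if column_map:
        colmap.update(column_map)
    tasks = []
    for name, path in paths.items():
        path = Path(path)
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        for canonical in _REQUIRED:
            col = colmap[canonical]
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        for feat in registry.names:
            if feat not in df.columns:
                raise ValueError(f"{path}: missing feature column {feat!r}")
        needed = [colmap[c] for c in _REQUIRED] + list(registry.names)
        missing_mask = df[needed].isna().any(axis=1)
        if missing_mask.any():
            rows = list(df.index[missing_mask])
            warnings.warn(
                f"{path}: dropped {len(rows)} row(s) with missing required values "
                f"(rows {rows[:20]}{'...' if len(rows) > 20 else ''})"
            )
            df = df.loc[~missing_mask]
        ev = df[colmap["event"]].to_numpy()
        if not np.all(np.isin(ev.astype(float), (0.0, 1.0))):
            raise ValueError(
                f"{path}: event column {colmap['event']!r} contains values other than 0/1"
            )
        time = df[colmap["time"]].to_numpy(dtype=float)
        if time_unit == "days":
            time = time / DAYS_PER_YEAR
        tasks.append(
            SurvivalTask(
                task_name=name,
                features=df[list(registry.names)].to_numpy(dtype=float),
                time=time,
                event=ev,
                subject_ids=df[colmap["id"]].to_numpy(),
            )
        )
    return MultiTaskDataset(tasks, registry)


def write_tasks(dataset: MultiTaskDataset, directory: str | Path, *, sep: str = ",") -> dict[str, Path]:
    """Write one delimited file per task (columns id, time, event, features)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for t in dataset.tasks:
        df = pd.DataFrame(t.features, columns=list(dataset.registry.names))
        df.insert(0, "event", t.event)
        df.insert(0, "time", t.time)
        df.insert(0, "id", t.subject_ids)
        path = directory / f"{t.task_name}.csv"
        df.to_csv(path, sep=sep, index=False)
        out[t.task_name] = path
    return out


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


def _center_scale(values: np.ndarray, name: str) -> tuple[float, float]:
    c = float(values.mean())
    s = float(values.std(ddof=1)) if values.size > 1 else 0.0
    if s == 0.0:
        warnings.warn(f"feature {name!r} has zero variance; centered only")
        return c, 1.0
    return c, s


def standardize(
    dataset: MultiTaskDataset, scope: Literal["pooled", "per_task"] = "pooled"
) -> MultiTaskDataset:
    """Center and scale continuous features to mean 0, sd 1 (sample sd, n-1).

    ``scope="pooled"`` estimates one center/scale from all tasks stacked;
    ``"per_task"`` estimates them within each cohort.  Binary features are
    left untouched.  Zero-variance features are centered only, with a warning.
    The transform parameters are stored on the returned dataset so they can be
    applied verbatim to new subjects with :func:`apply_standardization`.
    """
    cont = dataset.registry.continuous_mask
    p = dataset.n_features
    if scope == "pooled":
        stacked = np.vstack([t.features for t in dataset.tasks])
        center = np.zeros(p)
        scale = np.ones(p)
        for j in np.flatnonzero(cont):
            center[j], scale[j] = _center_scale(stacked[:, j], dataset.registry.names[j])
        std = Standardization(center=center, scale=scale, scope="pooled")
        new_tasks = [
            replace(t, features=(t.features - center) / scale) for t in dataset.tasks
        ]
    elif scope == "per_task":
        per_task = []
        new_tasks = []
        for t in dataset.tasks:
            center = np.zeros(p)
            scale = np.ones(p)
            for j in np.flatnonzero(cont):
                center[j], scale[j] = _center_scale(
                    t.features[:, j], f"{t.task_name}:{dataset.registry.names[j]}"
                )
            per_task.append((center, scale))
            new_tasks.append(replace(t, features=(t.features - center) / scale))
        std = Standardization(
            center=per_task[0][0],
            scale=per_task[0][1],
            scope="per_task",
            per_task=tuple(per_task),
        )
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return MultiTaskDataset([replace(t) for t in new_tasks], dataset.registry, std)


def apply_standardization(
    features: np.ndarray, std: Standardization, task_index: int = 0
) -> np.ndarray:
    """Apply a stored transform to new subjects (rows of ``features``)."""
    if std.scope == "per_task":
        assert std.per_task is not None
        center, scale = std.per_task[task_index]
    else:
        center, scale = std.center, std.scale
    return (np.asarray(features, dtype=float) - center) / scale


# ---------------------------------------------------------------------------
# Risk sets
# ---------------------------------------------------------------------------


@dataclass
class RiskSetIndex:
    """Sorted computational view of one task's risk-set structure.

    Subjects are sorted by follow-up time ascending (stable).  For each
    distinct event time ``T_i`` the risk set R(T_i) is every subject whose
    time is >= T_i, i.e. the sorted suffix starting at ``group_start``.
    Tied events at the same time form one tie group of size ``n_events_at``.
    """

    order: np.ndarray  # argsort of time (ascending, stable), length N
    time_sorted: np.ndarray
    event_sorted: np.ndarray
    event_times: np.ndarray  # distinct event times, ascending
    group_start: np.ndarray  # per event time: first sorted index with time >= T_i
    n_events_at: np.ndarray  # d_i, tied event counts
    event_positions: np.ndarray  # sorted positions of all event subjects

    @property
    def n_event_times(self) -> int:
        return len(self.event_times)

    def risk_set(self, i: int) -> np.ndarray:
        """Original subject indices of R(T_i) for the i-th distinct event time."""
        return self.order[self.group_start[i]:]

    def event_members(self, i: int) -> np.ndarray:
        """Original indices of subjects with an event exactly at event time i."""
        t = self.event_times[i]
        pos = self.event_positions[self.time_sorted[self.event_positions] == t]
        return self.order[pos]


def build_risk_sets(task: SurvivalTask) -> RiskSetIndex:
    """Index the ordered event times and their risk sets for one task.

    Raises if the task has no events (the partial likelihood is undefined).
    """
    if task.n_events == 0:
        raise ValueError(
            f"task {task.task_name!r} has zero events; partial likelihood undefined"
        )
    order = np.argsort(task.time, kind="stable")
    time_sorted = task.time[order]
    event_sorted = task.event[order]
    event_positions = np.flatnonzero(event_sorted == 1)
    event_times, first_idx = np.unique(time_sorted[event_positions], return_index=True)
    n_events_at = np.diff(np.append(first_idx, len(event_positions)))
    # first sorted position with time >= each event time
    group_start = np.searchsorted(time_sorted, event_times, side="left")
    return RiskSetIndex(
        order=order,
        time_sorted=time_sorted,
        event_sorted=event_sorted,
        event_times=event_times,
        group_start=group_start,
        n_events_at=n_events_at,
        event_positions=event_positions,
    )
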