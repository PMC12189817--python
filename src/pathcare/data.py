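"""Data model, file I/O and preprocessing for irregular multivariate EHR
visit sequences.

A patient is an ordered sequence of visits; each visit is an ``Nr``-vector
of clinical features (lab values, vital signs) together with an observed
mask, because in routine care most features are not measured at most
visits.  The preprocessing protocol is the standard one for clinical
time-series benchmarks:

1. forward-fill each feature from the patient's most recent observation,
2. z-score features using statistics fitted on the training split only,
3. impute entries that have never been observed for a patient (up to the
   given visit) with the dataset-level mean, which is 0 after z-scoring.

Every step is causal: the value at visit ``t`` depends only on the same
patient's observations at visits ``<= t`` plus train-split statistics.

Interchange format: a long-format CSV of observed entries
(``patient_id,visit_index,feature,value``) plus a labels CSV
(``patient_id,task,label,split``).  ``visit_index`` is an integer rank, not
a timestamp; the model consumes ordered visits only.  A trailing visit in
which *every* feature is unobserved is not representable in this format
(sequence length is inferred from the largest visit index).
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

RECORD_COLUMNS = ["patient_id", "visit_index", "feature", "value"]
LABEL_COLUMNS = ["patient_id", "task", "label", "split"]
SPLITS = ("train", "val", "test")


class CohortFormatError(ValueError):
    """Raised when an input table violates the interchange format."""


@dataclass(frozen=True)
class FeatureSchema:
    """Canonical feature order shared by every sequence in a cohort.

    ``kinds`` tags each feature as ``"numeric"`` (continuous measurement)
    or ``"binary-event"`` (0/1 occurrence); both are stored as floats and
    treated identically by preprocessing.
    """

    names: Tuple[str, ...]
    kinds: Tuple[str, ...] = ()

    def __post_init__(self):
        names = tuple(self.names)
        kinds = tuple(self.kinds) if self.kinds else ("numeric",) * len(names)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "kinds", kinds)
        if len(names) < 1:
            raise ValueError("schema needs at least one feature")
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if len(kinds) != len(names):
            raise ValueError("kinds must match names in length")
        bad = set(kinds) - {"numeric", "binary-event"}
        if bad:
            raise ValueError(f"unknown feature kinds: {sorted(bad)}")

    @property
    def n_features(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class VisitSequence:
    """One patient's ordered visit matrix with an observed mask.

    ``values`` is ``T x Nr``; entries where ``observed`` is False are NaN
    until imputation.  ``filled`` marks entries populated by forward fill
    (provenance: filled entries are defined but were not measured).
    """

    patient_id: str
    values: np.ndarray
    observed: np.ndarray
    labels: Dict[str, int] = field(default_factory=dict)
    filled: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x Nr matrix")
        if self.values.shape != self.observed.shape:
            raise ValueError("values and observed must share a shape")
        if self.values.shape[0] < 1:
            raise ValueError("a sequence needs at least one visit")
        for task, y in self.labels.items():
            if y not in (0, 1):
                raise ValueError(
                    f"label for task {task!r} must be 0 or 1, got {y!r}")
        if self.filled is None:
            self.filled = np.zeros_like(self.observed)

    @property
    def n_visits(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "VisitSequence":
        return VisitSequence(self.patient_id, self.values.copy(),
                             self.observed.copy(), dict(self.labels),
                             self.filled.copy())


@dataclass
class Cohort:
    """A set of visit sequences with a shared schema and split assignment."""

    schema: FeatureSchema
    patients: List[VisitSequence]
    split: Dict[str, str]

    def __post_init__(self):
        nr = self.schema.n_features
        for p in self.patients:
            if p.values.shape[1] != nr:
                raise ValueError(
                    f"patient {p.patient_id} has {p.values.shape[1]} "
                    f"features, schema has {nr}")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids")
        missing = set(ids) - set(self.split)
        if missing:
            raise ValueError(f"patients without split assignment: {sorted(missing)[:5]}")
        bad = set(self.split.values()) - set(SPLITS)
        if bad:
            raise ValueError(f"unknown split names: {sorted(bad)}")

    def patients_in(self, split: str) -> List[VisitSequence]:
        return [p for p in self.patients if self.split[p.patient_id] == split]

    def copy(self) -> "Cohort":
        return Cohort(self.schema, [p.copy() for p in self.patients],
                      dict(self.split))


@dataclass
class StandardizationStats:
    """Per-feature z-score statistics fitted on the training split.

    ``global_mean`` is the pre-standardization train mean, retained for
    the all-missing imputation rule (which becomes 0 after z-scoring).
    """

    mean: np.ndarray
    sd: np.ndarray
    global_mean: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        self.global_mean = np.asarray(self.global_mean, dtype=np.float64)
        if not np.all(self.sd > 0):
            raise ValueError("standard deviations must be positive")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cohort(records_path: str, labels_path: str,
                schema: FeatureSchema) -> Cohort:
    """Read a cohort from the long-format records + labels CSV pair."""
    rec = pd.read_csv(records_path, dtype={"patient_id": str, "feature": str},
                      float_precision="round_trip")
    lab = pd.read_csv(labels_path, dtype={"patient_id": str, "task": str,
                                          "split": str})
    for col in RECORD_COLUMNS:
        if col not in rec.columns:
            raise CohortFormatError(f"records table missing column {col!r}")
    for col in LABEL_COLUMNS:
        if col not in lab.columns:
            raise CohortFormatError(f"labels table missing column {col!r}")

    unknown = set(rec["feature"]) - set(schema.names)
    if unknown:
        raise CohortFormatError(
            f"unknown feature names in records: {sorted(unknown)[:5]}")
    dup = rec.duplicated(subset=["patient_id", "visit_index", "feature"])
    if dup.any():
        row = rec[dup].iloc[0]
        raise CohortFormatError(
            "duplicate record for (patient_id={}, visit_index={}, "
            "feature={})".format(row["patient_id"], row["visit_index"],
                                 row["feature"]))
    bad_labels = ~lab["label"].isin([0, 1])
    if bad_labels.any():
        row = lab[bad_labels].iloc[0]
        raise CohortFormatError(
            f"label must be 0 or 1, got {row['label']!r} for patient "
            f"{row['patient_id']!r}")

    col_of = {name: j for j, name in enumerate(schema.names)}
    patients: List[VisitSequence] = []
    split: Dict[str, str] = {}
    labels_by_pid: Dict[str, Dict[str, int]] = {}
    split_by_pid: Dict[str, str] = {}
    for _, row in lab.iterrows():
        pid = row["patient_id"]
        labels_by_pid.setdefault(pid, {})[row["task"]] = int(row["label"])
        prev = split_by_pid.setdefault(pid, row["split"])
        if prev != row["split"]:
            raise CohortFormatError(
                f"conflicting split assignment for patient {pid!r}")

    for pid, grp in rec.groupby("patient_id", sort=True):
        T = int(grp["visit_index"].max()) + 1
        values = np.full((T, schema.n_features), np.nan)
        observed = np.zeros((T, schema.n_features), dtype=bool)
        for _, row in grp.iterrows():
            t = int(row["visit_index"])
            j = col_of[row["feature"]]
            values[t, j] = float(row["value"])
            observed[t, j] = True
        patients.append(VisitSequence(pid, values, observed,
                                      labels_by_pid.get(pid, {})))
        if pid not in split_by_pid:
            raise CohortFormatError(f"patient {pid!r} has records but no "
                                    "labels/split row")
        split[pid] = split_by_pid[pid]
    return Cohort(schema, patients, split)


def write_cohort(cohort: Cohort, out_dir: str) -> Dict[str, str]:
    """Write a cohort to ``out_dir``; returns the file paths.

    Round-trips exactly with :func:`read_cohort` on observed values,
    masks, labels and splits.
    """
    if not cohort.patients:
        raise ValueError("cannot write an empty cohort")
    os.makedirs(out_dir, exist_ok=True)
    rec_rows = []
    lab_rows = []
    for p in cohort.patients:
        obs_t, obs_j = np.nonzero(p.observed)
        for t, j in zip(obs_t, obs_j):
            rec_rows.append((p.patient_id, int(t), cohort.schema.names[j],
                             repr(float(p.values[t, j]))))
        for task, y in sorted(p.labels.items()):
            lab_rows.append((p.patient_id, task, int(y),
                             cohort.split[p.patient_id]))
        if not p.labels:
            lab_rows.append((p.patient_id, "none", 0,
                             cohort.split[p.patient_id]))
    records_path = os.path.join(out_dir, "records.csv")
    labels_path = os.path.join(out_dir, "labels.csv")
    pd.DataFrame(rec_rows, columns=RECORD_COLUMNS).to_csv(
        records_path, index=False)
    pd.DataFrame(lab_rows, columns=LABEL_COLUMNS).to_csv(
        labels_path, index=False)
    return {"records": records_path, "labels": labels_path}


# ---------------------------------------------------------------------------
# Preprocessing protocol
# ---------------------------------------------------------------------------

def forward_fill(seq: VisitSequence) -> VisitSequence:
    """Carry each feature's most recent observed value forward.

    Entries with no prior observation stay undefined (no backward fill —
    that would leak future measurements into the past).  Idempotent.
    """
    out = seq.copy()
    T, nr = out.values.shape
    defined = out.observed | out.filled
    for j in range(nr):
        last = np.nan
        for t in range(T):
            if out.observed[t, j] and not out.filled[t, j]:
                last = out.values[t, j]
            elif not np.isnan(last):
                out.values[t, j] = last
                if not defined[t, j]:
                    out.filled[t, j] = True
    return out


def fit_standardization(cohort: Cohort) -> StandardizationStats:
    """Fit per-feature z-score statistics on the training split.

    Uses every defined (observed or forward-filled) entry of train-split
    patients.  Population (divide-by-n) standard deviation; features that
    are constant on the train split get sd := 1 so they standardize to 0.
    """
    nr = cohort.schema.n_features
    sums = np.zeros(nr)
    sqs = np.zeros(nr)
    counts = np.zeros(nr, dtype=np.int64)
    for p in cohort.patients_in("train"):
        defined = p.observed | p.filled
        for j in range(nr):
            v = p.values[defined[:, j], j]
            sums[j] += v.sum()
            sqs[j] += (v ** 2).sum()
            counts[j] += v.size
    never = counts == 0
    if never.any():
        names = [cohort.schema.names[j] for j in np.nonzero(never)[0]]
        raise ValueError(
            f"features never observed in the train split: {names}")
    mean = sums / counts
    var = sqs / counts - mean ** 2
    sd = np.sqrt(np.maximum(var, 0.0))
    sd[sd <= 1e-12] = 1.0
    return StandardizationStats(mean=mean, sd=sd, global_mean=mean.copy())


def apply_standardization(cohort: Cohort,
                          stats: StandardizationStats) -> Cohort:
    """Z-score every defined entry; masks are unchanged."""
    if stats.mean.shape[0] != cohort.schema.n_features:
        raise ValueError("standardization stats do not match the schema")
    out = cohort.copy()
    for p in out.patients:
        defined = p.observed | p.filled
        p.values = np.where(defined, (p.values - stats.mean) / stats.sd,
                            p.values)
    return out


def impute_all_missing(cohort: Cohort,
                       stats: StandardizationStats) -> Cohort:
    """Set entries still undefined after forward fill + z-scoring to the
    standardized dataset-level mean, i.e. 0.  After this, no NaN remains."""
    out = cohort.copy()
    for p in out.patients:
        defined = p.observed | p.filled
        p.values = np.where(defined, p.values, 0.0)
    return out


def truncate_visits(cohort: Cohort, max_T: int) -> Cohort:
    """Keep each patient's first ``min(T, max_T)`` visits; labels unchanged."""
    if max_T < 1:
        raise ValueError("max_T must be >= 1")
    out = cohort.copy()
    for p in out.patients:
        keep = min(p.n_visits, max_T)
        p.values = p.values[:keep]
        p.observed = p.observed[:keep]
        p.filled = p.filled[:keep]
    return out


def preprocess(cohort: Cohort, max_T: Optional[int] = None
               ) -> Tuple[Cohort, StandardizationStats]:
    """Run the full causal preprocessing pipeline.

    Order: optional visit-count truncation, forward fill, z-score with
    train-split statistics (fitted after filling), zero-imputation of
    never-observed entries.
    """
    if max_T is not None:
        cohort = truncate_visits(cohort, max_T)
    filled = Cohort(cohort.schema, [forward_fill(p) for p in cohort.patients],
                    dict(cohort.split))
    stats = fit_standardization(filled)
    standardized = apply_standardization(filled, stats)
    return impute_all_missing(standardized, stats), stats


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------

@dataclass
class Batch:
    """A padded mini-batch of fully-imputed sequences.

    ``values`` is ``B x T_max x Nr`` with zeros at padding positions;
    correctness downstream relies on ``lengths``, not the padding value.
    """

    patient_ids: List[str]
    values: np.ndarray
    lengths: np.ndarray
    labels: Dict[str, np.ndarray]

    @property
    def size(self) -> int:
        return len(self.patient_ids)

    @property
    def max_T(self) -> int:
        return self.values.shape[1]

    def last_records(self) -> np.ndarray:
        """The last non-padding visit record of each patient (B x Nr)."""
        return self.values[np.arange(self.size), self.lengths - 1]


def batch_cohort(cohort: Cohort, split: str, batch_size: int,
                 shuffle_seed: Optional[int] = None) -> Iterator[Batch]:
    """Yield padded batches of ≤ ``batch_size`` patients from one split.

    With ``shuffle_seed`` set, patient order is shuffled reproducibly;
    otherwise patients appear in cohort order.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    patients = cohort.patients_in(split)
    for p in patients:
        if np.isnan(p.values).any():
            raise ValueError(
                f"patient {p.patient_id} has unimputed entries; run "
                "preprocessing first")
    order = np.arange(len(patients))
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        rng.shuffle(order)
    tasks = sorted({t for p in patients for t in p.labels})
    for start in range(0, len(patients), batch_size):
        chunk = [patients[i] for i in order[start:start + batch_size]]
        lengths = np.array([p.n_visits for p in chunk], dtype=np.int64)
        T = int(lengths.max())
        nr = cohort.schema.n_features
        values = np.zeros((len(chunk), T, nr))
        for i, p in enumerate(chunk):
            values[i, :p.n_visits] = p.values
        labels = {task: np.array([p.labels.get(task, 0) for p in chunk],
                                 dtype=np.int64) for task in tasks}
        yield Batch([p.patient_id for p in chunk], values, lengths, labels)


def import_stub(*args, **kwargs):
    """Mapping contract for clinical-standard sources (FHIR/OMOP).

    Not implemented.  An importer must produce the long-format records
    table (one row per observed measurement: patient id, integer visit
    rank, feature name from the cohort schema, numeric value) and the
    labels table (one row per patient and task with a 0/1 label and a
    train/val/test split).  Categorical codes must be resolved to numeric
    or binary-event features before import.
    """
    raise NotImplementedError(import_stub.__doc__)
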