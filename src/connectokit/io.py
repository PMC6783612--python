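"""Connectome containers and file I/O.

A connectome is stored on disk as a headerless delimited-text matrix
(whitespace- or comma-separated, auto-detected), one file per subject.
Node identity lives in a separate label table (``index,region_name``),
so matrix files stay free of header-parsing ambiguity.  A cohort is
described by a CSV manifest with columns
``subject_id,group,alsfrs_r,duration_months`` (clinical columns empty
for controls) and optional ``age``/``sex`` demographic columns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import CohortError, FormatError, IntegrityError

GROUPS = ("patient", "control")

#: tolerance under which a stored matrix is considered symmetric and is
#: symmetrized by averaging with its transpose
SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class ClinicalRecord:
    """Clinical covariates of one ALS patient.

    ``alsfrs_r`` is the revised ALS Functional Rating Scale total
    (0-48, higher = less disability); ``duration_months`` is the
    disease duration at assessment.  The disease progression rate is
    ``(48 - ALSFRS-R) / duration`` in points per month.
    """

    alsfrs_r: float
    duration_months: float

    def __post_init__(self):
        if not 0 <= self.alsfrs_r <= 48:
            raise IntegrityError(
                f"ALSFRS-R must lie in [0, 48], got {self.alsfrs_r}")
        if not self.duration_months > 0:
            raise IntegrityError(
                f"disease duration must be positive, got {self.duration_months}")

    @property
    def progression_rate(self) -> float:
        return (48.0 - self.alsfrs_r) / self.duration_months


class ConnectivityMatrix:
    """One subject's symmetric FA-weighted adjacency matrix.

    Weights are mean fractional anisotropy per connection, in [0, 1);
    an entry of exactly 0 means "no edge"; the diagonal is zero.
    Asymmetries up to :data:`SYMMETRY_TOL` are averaged away; anything
    larger raises :class:`IntegrityError`.
    """

    __slots__ = ("weights", "node_ids", "subject_id")

    def __init__(self, weights, node_ids=None, subject_id="", *, where=""):
        w = np.asarray(weights, dtype=float)
        src = f" in {where}" if where else ""
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise FormatError(f"matrix{src} is not square: shape {w.shape}")
        if not np.all(np.isfinite(w)):
            i, j = np.argwhere(~np.isfinite(w))[0]
            raise IntegrityError(f"non-finite weight at [{i}][{j}]{src}")
        asym = np.abs(w - w.T).max() if w.size else 0.0
        if asym > SYMMETRY_TOL:
            i, j = np.unravel_index(np.abs(w - w.T).argmax(), w.shape)
            raise IntegrityError(
                f"matrix{src} asymmetric at [{i}][{j}] (|w_ij - w_ji| = {asym:g})")
        w = (w + w.T) / 2.0
        d = np.abs(np.diag(w))
        if w.size and d.max() > 0:
            i = int(d.argmax())
            raise IntegrityError(f"nonzero diagonal entry at [{i}][{i}]{src}")
        if w.size and w.min() < 0:
            i, j = np.unravel_index(w.argmin(), w.shape)
            raise IntegrityError(f"negative weight at [{i}][{j}]{src}")
        if w.size and w.max() >= 1.0:
            i, j = np.unravel_index(w.argmax(), w.shape)
            raise IntegrityError(
                f"FA weight must be < 1, got {w.max():g} at [{i}][{j}]{src}")
        self.weights = w
        n = w.shape[0]
        if node_ids is None:
            node_ids = [f"region_{k:03d}" for k in range(n)]
        node_ids = list(node_ids)
        if len(node_ids) != n:
            raise FormatError(
                f"{len(node_ids)} node labels for a {n}-node matrix{src}")
        self.node_ids = node_ids
        self.subject_id = subject_id

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def copy(self) -> "ConnectivityMatrix":
        return ConnectivityMatrix(self.weights.copy(), list(self.node_ids),
                                  self.subject_id)

    def __eq__(self, other):
        return (isinstance(other, ConnectivityMatrix)
                and np.array_equal(self.weights, other.weights)
                and self.node_ids == other.node_ids)

    def __repr__(self):
        return (f"ConnectivityMatrix(subject_id={self.subject_id!r}, "
                f"n_nodes={self.n_nodes}, n_edges={self.n_edges})")


@dataclass
class Subject:
    subject_id: str
    group: str
    matrix: ConnectivityMatrix
    clinical: ClinicalRecord | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise CohortError(
                f"subject {self.subject_id!r}: unknown group {self.group!r}; "
                f"allowed labels: {GROUPS}")


@dataclass
class Cohort:
    """An ordered collection of subjects sharing one parcellation."""

    subjects: list[Subject]
    node_ids: list[str] = field(default_factory=list)
    demographics: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.subjects:
            raise CohortError("cohort has no subjects")
        if not self.node_ids:
            self.node_ids = list(self.subjects[0].matrix.node_ids)
        n = len(self.node_ids)
        bad = [s.subject_id for s in self.subjects if s.matrix.n_nodes != n]
        if bad:
            ref = self.subjects[0].subject_id
            raise CohortError(
                f"inconsistent node count: subjects {bad} differ from "
                f"{ref!r} ({n} nodes)")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate subject ids in cohort")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def groups(self) -> pd.Series:
        return pd.Series({s.subject_id: s.group for s in self.subjects})

    def subjects_in(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == group]

    @property
    def patients(self) -> list[Subject]:
        return self.subjects_in("patient")

    @property
    def controls(self) -> list[Subject]:
        return self.subjects_in("control")

    def stack(self) -> np.ndarray:
        """All weight matrices as one (n_subjects, N, N) array."""
        return np.stack([s.matrix.weights for s in self.subjects])

    def is_patient_mask(self) -> np.ndarray:
        return np.array([s.group == "patient" for s in self.subjects])

    def clinical_frame(self) -> pd.DataFrame:
        """Patient clinical covariates, one row per patient with a record."""
        rows = []
        for s in self.subjects:
            if s.clinical is not None:
                rows.append({"subject_id": s.subject_id,
                             "alsfrs_r": s.clinical.alsfrs_r,
                             "duration_months": s.clinical.duration_months,
                             "progression_rate": s.clinical.progression_rate})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# matrix files


def _detect_delimiter(path: str) -> str | None:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "," if "," in line else None
    raise FormatError(f"{path}: empty matrix file")


def read_connectivity_matrix(path, node_labels=None,
                             subject_id: str | None = None) -> ConnectivityMatrix:
    """Read and validate a delimited-text connectivity matrix."""
    delim = _detect_delimiter(path)
    try:
        w = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse as numeric matrix ({exc})") from exc
    if subject_id is None:
        subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    return ConnectivityMatrix(w, node_labels, subject_id, where=str(path))


def write_connectivity_matrix(matrix: ConnectivityMatrix, path) -> None:
    """Write a matrix as whitespace-delimited text at full precision."""
    np.savetxt(path, matrix.weights, fmt="%.17g", delimiter=" ")


# ---------------------------------------------------------------------------
# node labels


def read_node_labels(path) -> list[str]:
    df = pd.read_csv(path)
    for col in ("index", "region_name"):
        if col not in df.columns:
            raise FormatError(f"{path}: label file needs columns "
                              f"'index,region_name', got {list(df.columns)}")
    df = df.sort_values("index")
    idx = df["index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(idx))):
        raise FormatError(f"{path}: label indices must be 0..N-1 contiguous")
    return df["region_name"].astype(str).tolist()


def write_node_labels(node_ids: Iterable[str], path) -> None:
    pd.DataFrame({"index": range(len(list(node_ids))),
                  "region_name": list(node_ids)}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohorts

MANIFEST_COLUMNS = ("subject_id", "group", "alsfrs_r", "duration_months")


def load_cohort(manifest_path, matrix_dir, labels_path=None) -> Cohort:
    """Load a cohort from a manifest CSV plus per-subject matrix files.

    Each manifest row must reference ``<matrix_dir>/<subject_id>.txt``
    (or an explicit ``matrix_file`` column).  Clinical columns may be
    empty for controls; ALSFRS-R outside [0, 48] or non-positive
    duration raises :class:`IntegrityError`.
    """
    mf = pd.read_csv(manifest_path)
    for col in ("subject_id", "group"):
        if col not in mf.columns:
            raise FormatError(f"{manifest_path}: manifest must have a "
                              f"'{col}' column")
    labels = read_node_labels(labels_path) if labels_path else None
    subjects = []
    for _, row in mf.iterrows():
        sid = str(row["subject_id"])
        grp = str(row["group"])
        if grp not in GROUPS:
            raise CohortError(
                f"{manifest_path}: subject {sid!r} has group {grp!r}; "
                f"allowed labels: {GROUPS}")
        fname = row.get("matrix_file")
        if fname is None or (isinstance(fname, float) and np.isnan(fname)):
            fname = f"{sid}.txt"
        mpath = os.path.join(str(matrix_dir), str(fname))
        if not os.path.exists(mpath):
            raise FormatError(f"matrix file for subject {sid!r} not found: {mpath}")
        matrix = read_connectivity_matrix(mpath, labels, subject_id=sid)
        clinical = None
        a = row.get("alsfrs_r")
        d = row.get("duration_months")
        if a is not None and d is not None and pd.notna(a) and pd.notna(d):
            try:
                clinical = ClinicalRecord(float(a), float(d))
            except IntegrityError as exc:
                raise IntegrityError(f"subject {sid!r}: {exc}") from exc
        subjects.append(Subject(sid, grp, matrix, clinical))
    demo_cols = [c for c in ("age", "sex", "handedness") if c in mf.columns]
    demographics = None
    if demo_cols:
        demographics = mf[["subject_id", "group"] + demo_cols].copy()
    return Cohort(subjects, demographics=demographics)


def write_cohort(cohort: Cohort, outdir, truth: Mapping | None = None) -> None:
    """Write matrices, manifest, node labels (and optionally a truth record)."""
    os.makedirs(outdir, exist_ok=True)
    mdir = os.path.join(str(outdir), "matrices")
    os.makedirs(mdir, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        write_connectivity_matrix(s.matrix, os.path.join(mdir, f"{s.subject_id}.txt"))
        rows.append({
            "subject_id": s.subject_id,
            "group": s.group,
            "alsfrs_r": s.clinical.alsfrs_r if s.clinical else "",
            "duration_months": s.clinical.duration_months if s.clinical else "",
        })
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    if cohort.demographics is not None:
        manifest = manifest.merge(
            cohort.demographics.drop(columns=["group"]), on="subject_id", how="left")
    manifest.to_csv(os.path.join(str(outdir), "manifest.csv"), index=False)
    write_node_labels(cohort.node_ids, os.path.join(str(outdir), "node_labels.csv"))
    if truth is not None:
        import yaml

        with open(os.path.join(str(outdir), "truth.yaml"), "w") as fh:
            yaml.safe_dump(_plain(truth), fh, sort_keys=True)


def _plain(obj):
    """Recursively convert numpy scalars/arrays so YAML/JSON can store them."""
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
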