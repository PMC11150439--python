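"""Cohort loading, validation, and global signal regression.

Inputs are already-parcellated region x time matrices (headerless TSV,
T rows x N columns, one file per subject/session) plus a manifest TSV with
columns ``subject_id, session_id, condition, mean_fd, path``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import TimeSeriesSession

__all__ = ["SessionDesign", "CohortDataset", "load_cohort", "global_signal_regress"]


@dataclasses.dataclass(frozen=True)
class SessionDesign:
    """Declared session roles: which pair is test-retest and which session
    (if any) carries the perturbed condition."""

    retest_pair: tuple[str, str] = ("rest1", "rest2")
    condition_session: str | None = "perturbed"


@dataclasses.dataclass
class CohortDataset:
    """A named, validated collection of sessions sharing one node set."""

    name: str
    sessions: list[TimeSeriesSession]
    design: SessionDesign = dataclasses.field(default_factory=SessionDesign)

    def __post_init__(self) -> None:
        if not self.sessions:
            raise ValueError("dataset has no sessions")
        n_nodes = {s.n_nodes for s in self.sessions}
        if len(n_nodes) != 1:
            raise ValueError(f"sessions disagree on node count: {sorted(n_nodes)}")
        self._index = {(s.subject_id, s.session_id): s for s in self.sessions}
        if len(self._index) != len(self.sessions):
            raise ValueError("duplicate (subject_id, session_id) in dataset")
        a, b = self.design.retest_pair
        for subject in self.subjects:
            for required in (a, b):
                if (subject, required) not in self._index:
                    raise ValueError(
                        f"design error: subject {subject!r} lacks session {required!r}"
                    )

    @property
    def n_nodes(self) -> int:
        return self.sessions[0].n_nodes

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sessions:
            seen.setdefault(s.subject_id, None)
        return list(seen)

    def session(self, subject_id: str, session_id: str) -> TimeSeriesSession:
        return self._index[(subject_id, session_id)]

    def retest_pairs(self) -> list[tuple[TimeSeriesSession, TimeSeriesSession]]:
        a, b = self.design.retest_pair
        return [(self.session(s, a), self.session(s, b)) for s in self.subjects]

    def condition_pairs(self) -> list[tuple[TimeSeriesSession, TimeSeriesSession]]:
        """Awake-vs-perturbed pairs: first retest session against the
        condition session of the same subject."""
        if self.design.condition_session is None:
            raise ValueError(f"dataset {self.name!r} declares no condition session")
        a, _ = self.design.retest_pair
        c = self.design.condition_session
        return [(self.session(s, a), self.session(s, c)) for s in self.subjects]


def _validate_matrix(mat: np.ndarray, path: str) -> None:
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError(f"format error in {path}: expected a T x N matrix, T,N >= 2")
    if not np.all(np.isfinite(mat)):
        raise ValueError(f"format error in {path}: NaN or Inf values present")
    variances = mat.var(axis=0)
    dead = np.flatnonzero(variances == 0)
    if dead.size:
        raise ValueError(
            f"format error in {path}: constant column(s) {dead.tolist()} (zero variance)"
        )


def load_cohort(
    manifest_path: str | Path,
    name: str | None = None,
    design: SessionDesign | None = None,
) -> CohortDataset:
    """Load and validate a cohort from a manifest TSV.

    Matrix paths in the manifest are resolved relative to the manifest's
    directory.  Shape mismatches, non-finite values, constant columns, and
    missing design sessions all raise ``ValueError``.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(
        manifest_path,
        sep="\t",
        dtype={"subject_id": str, "session_id": str},
        float_precision="round_trip",
    )
    required = {"subject_id", "session_id", "condition", "mean_fd", "path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    sessions = []
    for row in table.itertuples(index=False):
        path = manifest_path.parent / row.path
        mat = np.loadtxt(path, delimiter="\t", ndmin=2)
        _validate_matrix(mat, str(path))
        sessions.append(
            TimeSeriesSession(
                subject_id=row.subject_id,
                session_id=row.session_id,
                condition=row.condition,
                data=mat,
                mean_fd=float(row.mean_fd),
            )
        )
    return CohortDataset(
        name=name or manifest_path.parent.name,
        sessions=sessions,
        design=design or SessionDesign(),
    )


def global_signal_regress(session: TimeSeriesSession) -> TimeSeriesSession:
    """Regress the global signal out of every node's time series.

    The global signal g(t) is the unweighted mean across the N columns at
    each timepoint.  Each column is replaced by the residual of its
    least-squares regression on [intercept, g], so residuals are
    mean-centred and exactly uncorrelated with g.
    """
    data = session.data
    if data.shape[0] <= 2:
        raise ValueError("global signal regression needs T > 2")
    g = data.mean(axis=1)
    if np.ptp(g) == 0:
        raise ValueError("degenerate global signal: constant across timepoints")
    design = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    residuals = data - design @ beta
    return TimeSeriesSession(
        subject_id=session.subject_id,
        session_id=session.session_id,
        condition=session.condition,
        data=residuals,
        mean_fd=session.mean_fd,
    )
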