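"""Synthetic multi-subject, multi-session BOLD-like cohort generator.

Emulates the statistical structure of a parcellated resting-state fMRI
test-retest study: every subject contributes two rest sessions drawn from a
subject-specific modular covariance, plus one "perturbed" session whose
modular structure is attenuated (an anaesthesia-like condition contrast).
Head motion enters as framewise-displacement-scaled additive white noise.

The generative model is linear-Gaussian: region time series are i.i.d.
draws from a zero-mean multivariate normal whose correlation matrix has a
block (module) structure, plus white observation noise.  There is no
haemodynamic model, autocorrelation, or scanner drift.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

_EIG_FLOOR = 1e-6

__all__ = [
    "CohortSpec",
    "TimeSeriesSession",
    "make_base_covariance",
    "perturb_for_subject",
    "condition_transform",
    "simulate_session",
    "generate_cohort",
    "write_cohort",
]


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults describe a desk-scale resting-state-like study: 15 subjects,
    40 regions in 4 modules, 200 samples per session, moderate modular
    correlation structure, a mid-sized condition contrast, and a typical
    framewise-displacement distribution (mean 0.15 mm, SD 0.08 mm).
    """

    n_subjects: int = 15
    n_nodes: int = 40
    n_timepoints: int = 200
    n_modules: int = 4
    within_strength: float = 0.5
    between_strength: float = 0.1
    subject_effect: float = 0.3
    session_noise: float = 0.5
    condition_effect: float = 0.5
    motion_coupling: float = 0.0
    fd_mean: float = 0.15
    fd_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_nodes < 2 or self.n_timepoints < 2:
            raise ValueError("cohort dimensions too small")
        if self.n_modules < 1 or self.n_modules > self.n_nodes:
            raise ValueError("n_modules must be in [1, n_nodes]")
        if not (0.0 <= self.within_strength < 1.0):
            raise ValueError("within_strength must lie in [0, 1)")
        if not (0.0 <= self.between_strength <= self.within_strength):
            raise ValueError(
                "between_strength must satisfy 0 <= between <= within < 1"
            )
        if self.within_strength > 0 and self.between_strength >= self.within_strength:
            raise ValueError("between_strength must be < within_strength")
        if self.subject_effect < 0 or self.session_noise < 0 or self.motion_coupling < 0:
            raise ValueError("effect magnitudes must be non-negative")
        if not (0.0 <= self.condition_effect <= 1.0):
            raise ValueError("condition_effect must lie in [0, 1]")
        if self.fd_sd <= 0 or self.fd_mean < 0:
            raise ValueError("fd distribution must have fd_mean >= 0, fd_sd > 0")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclasses.dataclass
class TimeSeriesSession:
    """One subject/session parcellated time-series matrix (T x N)."""

    subject_id: str
    session_id: str
    condition: str
    data: np.ndarray
    mean_fd: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError("session data must be a T x N matrix with T, N >= 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("session data contains non-finite values")
        if self.condition not in ("rest", "perturbed"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.mean_fd < 0:
            raise ValueError("mean_fd must be non-negative")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


def _module_labels(n_nodes: int, n_modules: int) -> np.ndarray:
    """Assign nodes to modules as evenly as possible (sizes differ by <= 1)."""
    sizes = [len(chunk) for chunk in np.array_split(np.arange(n_nodes), n_modules)]
    return np.repeat(np.arange(n_modules), sizes)


def _project_to_correlation(mat: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at the SPD floor and renormalise to unit diagonal."""
    sym = (mat + mat.T) / 2.0
    for _ in range(50):
        vals, vecs = np.linalg.eigh(sym)
        if vals[0] >= _EIG_FLOOR:
            break
        vals = np.clip(vals, _EIG_FLOOR, None)
        sym = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(sym))
        sym = sym / np.outer(d, d)
        np.fill_diagonal(sym, 1.0)
    return sym


def make_base_covariance(spec: CohortSpec) -> np.ndarray:
    """Block correlation matrix: unit diagonal, ``within_strength`` inside
    modules, ``between_strength`` across modules; ridge-regularised to SPD."""
    labels = _module_labels(spec.n_nodes, spec.n_modules)
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, spec.within_strength, spec.between_strength).astype(float)
    np.fill_diagonal(cov, 1.0)
    # block structure with between <= within < 1 is SPD in practice; the
    # ridge loop guards degenerate parameterisations
    while np.linalg.eigvalsh(cov)[0] < _EIG_FLOOR:
        cov[np.diag_indices_from(cov)] += 10 * _EIG_FLOOR
        cov /= cov[0, 0]
    return cov


def perturb_for_subject(
    base: np.ndarray, subject_effect: float, rng: np.random.Generator
) -> np.ndarray:
    """Subject-specific covariance: base plus a random symmetric perturbation
    whose entries have standard deviation ``subject_effect`` (the SD of the
    subject-specific deviation of each correlation entry), projected back to
    a unit-diagonal SPD correlation-like matrix."""
    if subject_effect < 0:
        raise ValueError("subject_effect must be non-negative")
    if subject_effect == 0:
        return base.copy()
    n = base.shape[0]
    noise = rng.standard_normal((n, n))
    sym = (noise + noise.T) / np.sqrt(2.0)
    perturbed = base + subject_effect * sym
    np.fill_diagonal(perturbed, 1.0)
    return _project_to_correlation(perturbed)


def condition_transform(cov: np.ndarray, condition_effect: float) -> np.ndarray:
    """Attenuate modular contrast toward the global mean off-diagonal value.

    Returns ``(1 - e) * cov + e * M`` where M is the compound-symmetric
    matrix whose off-diagonal entries all equal the mean off-diagonal of
    ``cov``; e = 0 is the identity transform, e = 1 erases all modular
    contrast.  Result is re-projected to SPD with unit diagonal if needed.
    """
    if not (0.0 <= condition_effect <= 1.0):
        raise ValueError("condition_effect must lie in [0, 1]")
    if condition_effect == 0:
        return cov.copy()
    n = cov.shape[0]
    off = cov[~np.eye(n, dtype=bool)]
    target = np.full((n, n), off.mean())
    np.fill_diagonal(target, 1.0)
    out = (1.0 - condition_effect) * cov + condition_effect * target
    if np.linalg.eigvalsh(out)[0] < _EIG_FLOOR:
        out = _project_to_correlation(out)
    return out


def _truncated_fd(spec: CohortSpec, rng: np.random.Generator) -> float:
    a = (0.0 - spec.fd_mean) / spec.fd_sd
    return float(
        stats.truncnorm.rvs(a, np.inf, loc=spec.fd_mean, scale=spec.fd_sd, random_state=rng)
    )


def simulate_session(
    cov: np.ndarray,
    spec: CohortSpec,
    condition: str,
    rng: np.random.Generator,
    subject_id: str = "sub001",
    session_id: str = "rest1",
) -> TimeSeriesSession:
    """Draw T i.i.d. multivariate-Gaussian samples with covariance ``cov``
    plus white observation noise whose SD grows with the session's mean
    framewise displacement when ``motion_coupling`` > 0."""
    cov = np.asarray(cov, dtype=float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    mean_fd = _truncated_fd(spec, rng)
    noise_sd = max(0.0, spec.session_noise + spec.motion_coupling * (mean_fd - spec.fd_mean))
    data = rng.standard_normal((spec.n_timepoints, cov.shape[0])) @ chol.T
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return TimeSeriesSession(
        subject_id=subject_id,
        session_id=session_id,
        condition=condition,
        data=data,
        mean_fd=mean_fd,
    )


def _stream(seed: int, subject_id: str, session_id: str) -> np.random.Generator:
    """Deterministic per-(subject, session) RNG stream.

    Streams are keyed by CRC32 hashes of the labels so reproducibility does
    not depend on iteration order.
    """
    entropy = [seed, zlib.crc32(subject_id.encode()), zlib.crc32(session_id.encode())]
    return np.random.default_rng(np.random.SeedSequence(entropy))


SESSION_LAYOUT = (("rest1", "rest"), ("rest2", "rest"), ("perturbed", "perturbed"))


def generate_cohort(spec: CohortSpec) -> list[TimeSeriesSession]:
    """Full cohort: per subject, two rest sessions from the subject's own
    covariance and one perturbed session from its condition-transformed
    covariance.  Bit-deterministic given the spec (including seed)."""
    base = make_base_covariance(spec)
    sessions: list[TimeSeriesSession] = []
    for i in range(spec.n_subjects):
        subject_id = f"sub{i + 1:03d}"
        cov_subject = perturb_for_subject(
            base, spec.subject_effect, _stream(spec.seed, subject_id, "covariance")
        )
        cov_perturbed = condition_transform(cov_subject, spec.condition_effect)
        for session_id, condition in SESSION_LAYOUT:
            cov = cov_perturbed if condition == "perturbed" else cov_subject
            sessions.append(
                simulate_session(
                    cov,
                    spec,
                    condition,
                    _stream(spec.seed, subject_id, session_id),
                    subject_id=subject_id,
                    session_id=session_id,
                )
            )
    return sessions


def write_cohort(sessions: list[TimeSeriesSession], outdir: str | Path) -> Path:
    """Write one headerless TSV matrix per session plus a manifest TSV.

    Returns the manifest path.  Matrices are written at full double
    precision so a read round-trips exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sessions:
        fname = f"{s.subject_id}_{s.session_id}.tsv"
        np.savetxt(outdir / fname, s.data, delimiter="\t", fmt="%.17g")
        rows.append(
            {
                "subject_id": s.subject_id,
                "session_id": s.session_id,
                "condition": s.condition,
                "mean_fd": repr(s.mean_fd),
                "path": fname,
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
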