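"""Kinematic PCA: principal movements, scores and their derivatives.

A PCA of the concatenated normalized posture matrix yields an
orthonormal basis of posture space.  Each eigenvector ``PC_k`` defines
a principal movement (PM); projecting a trial onto it gives the
principal-position score series ``PP_k(t)`` whose first and second time
derivatives are the principal velocities ``PV_k(t)`` and accelerations
``PA_k(t)``.  The relative eigenvalue ``EV_k`` is the fraction of total
posture-space variance the component explains; only components
explaining more than the average column share (1/n_columns, i.e. 1.2%
for 84 columns) are retained, and their robustness is screened by a
leave-one-subject-out refit of the basis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocessing import PostureMatrix

__all__ = [
    "PrincipalMovementBasis",
    "PMTimeSeries",
    "fit_pma",
    "project",
    "differentiate",
    "select_pms",
    "loo_crossvalidate",
    "pm_extreme_postures",
    "pm_series_for_matrix",
]


@dataclass
class PrincipalMovementBasis:
    """Mean posture, orthonormal PC vectors and their (relative) eigenvalues."""

    mean_posture: np.ndarray
    pc_vectors: np.ndarray  # (k, n_columns), rows orthonormal
    eigenvalues: np.ndarray  # variances, non-increasing
    n_rows: int = 0

    @property
    def rel_ev(self) -> np.ndarray:
        """Relative eigenvalues as fractions of total variance."""
        return self.eigenvalues / self.eigenvalues.sum()

    @property
    def rel_ev_pct(self) -> np.ndarray:
        return 100.0 * self.rel_ev

    @property
    def k(self) -> int:
        return self.pc_vectors.shape[0]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mean_posture": self.mean_posture.tolist(),
            "pc_vectors": self.pc_vectors.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_rows": self.n_rows,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "PrincipalMovementBasis":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["mean_posture"]), np.array(d["pc_vectors"]),
                   np.array(d["eigenvalues"]), d.get("n_rows", 0))


@dataclass
class PMTimeSeries:
    """One trial's PP/PV/PA score series for each retained PM."""

    subject_id: str
    group: str
    condition: str
    pp: np.ndarray  # (frames, k)
    pv: np.ndarray
    pa: np.ndarray
    rate_hz: float


def _sign_fix(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude loading positive."""
    out = vectors.copy()
    for i, v in enumerate(out):
        j = np.argmax(np.abs(v))
        if v[j] < 0:
            out[i] = -v
    return out


def fit_pma(X: PostureMatrix | np.ndarray) -> PrincipalMovementBasis:
    """Eigendecompose the covariance of the posture matrix.

    The matrix is expected to be centered/weighted already; no per-column
    re-standardization is applied (the height and segment-mass weighting
    is the normalization).  Eigenvalues use the 1/(n-1) covariance
    convention; eigenvector signs follow the largest-loading-positive
    rule so refits are comparable.
    """
    data = X.data if isinstance(X, PostureMatrix) else np.asarray(X, float)
    if not np.isfinite(data).all():
        raise ValueError("posture matrix contains non-finite values")
    n, p = data.shape
    mean = data.mean(axis=0)
    C = np.cov(data, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    vectors = _sign_fix(evecs[:, order].T)
    return PrincipalMovementBasis(mean, vectors, evals, n_rows=n)


def project(trial_block: np.ndarray, basis: PrincipalMovementBasis) -> np.ndarray:
    """Score a (frames x columns) block on the PM basis: PP = (X - mean) PCᵀ."""
    block = np.asarray(trial_block, float)
    if block.shape[1] != basis.pc_vectors.shape[1]:
        raise ValueError(
            f"block has {block.shape[1]} columns, basis expects {basis.pc_vectors.shape[1]}"
        )
    return (block - basis.mean_posture) @ basis.pc_vectors.T


def reconstruct(pp: np.ndarray, basis: PrincipalMovementBasis) -> np.ndarray:
    """Inverse of :func:`project` (exact when k equals the matrix rank)."""
    return pp @ basis.pc_vectors + basis.mean_posture


def differentiate(pp: np.ndarray, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Principal velocities and accelerations by central differences.

    Interior: ``pv[t] = (pp[t+1] - pp[t-1]) * rate / 2`` and
    ``pa[t] = (pp[t+1] - 2 pp[t] + pp[t-1]) * rate**2``; endpoints use
    one-sided first/second-order stencils so the outputs keep the input
    length.
    """
    pp = np.asarray(pp, float)
    if pp.shape[0] < 5:
        raise ValueError("need at least 5 frames to differentiate")
    pv = np.empty_like(pp)
    pa = np.empty_like(pp)
    pv[1:-1] = (pp[2:] - pp[:-2]) * (rate_hz / 2.0)
    pv[0] = (pp[1] - pp[0]) * rate_hz
    pv[-1] = (pp[-1] - pp[-2]) * rate_hz
    pa[1:-1] = (pp[2:] - 2 * pp[1:-1] + pp[:-2]) * rate_hz**2
    pa[0] = (pp[2] - 2 * pp[1] + pp[0]) * rate_hz**2
    pa[-1] = (pp[-1] - 2 * pp[-2] + pp[-3]) * rate_hz**2
    return pv, pa


def select_pms(rel_ev: np.ndarray, n_columns: int) -> np.ndarray:
    """Indices of PMs whose variance share strictly exceeds 1/n_columns.

    On average each input column contributes 1/n_columns of the overall
    variance (1.2% for 84 columns), so components below that share carry
    less structure than a single raw coordinate.
    """
    rel_ev = np.asarray(rel_ev, float)
    if rel_ev.max() > 1.001:  # percent scale passed in
        rel_ev = rel_ev / 100.0
    return np.flatnonzero(rel_ev > 1.0 / n_columns)


def selection_threshold_pct(n_columns: int) -> float:
    """The retention threshold in percent (100/n_columns)."""
    return 100.0 / n_columns


def loo_crossvalidate(
    X: PostureMatrix,
    basis: PrincipalMovementBasis,
    k: int,
    angle_limit_deg: float = 15.0,
    matching: str = "rank",
) -> dict:
    """Leave-one-subject-out robustness of the first ``k`` PC orientations.

    For each subject, the PCA is refit on the remaining subjects' rows;
    components are matched to the full-data basis by eigenvalue rank
    (``matching='rank'``) or greedily by maximum |dot| for
    near-degenerate spectra (``matching='greedy'``).  The angle between
    matched eigenvectors, ``arccos |PC_full · PC_loo|``, is aggregated
    as a per-PM maximum over subjects; a PM is robust when that maximum
    stays below ``angle_limit_deg``.
    """
    subjects = sorted({s for _, _, s, _ in X.row_ledger})
    if len(subjects) < 3:
        raise ValueError("leave-one-out requires at least 3 subjects")
    max_angle = np.zeros(k)
    for subj in subjects:
        drop = X.rows_for(subj)
        keep = np.setdiff1d(np.arange(X.data.shape[0]), drop, assume_unique=True)
        sub = fit_pma(X.data[keep])
        full_vecs = basis.pc_vectors[:k]
        if matching == "rank":
            loo_vecs = sub.pc_vectors[:k]
        elif matching == "greedy":
            dots = np.abs(full_vecs @ sub.pc_vectors.T)
            loo_vecs = np.empty_like(full_vecs)
            taken: set[int] = set()
            for i in range(k):
                order = np.argsort(dots[i])[::-1]
                j = next(int(c) for c in order if int(c) not in taken)
                taken.add(j)
                loo_vecs[i] = sub.pc_vectors[j]
        else:
            raise ValueError(f"unknown matching rule {matching!r}")
        cosines = np.clip(np.abs(np.sum(full_vecs * loo_vecs, axis=1)), 0.0, 1.0)
        max_angle = np.maximum(max_angle, np.degrees(np.arccos(cosines)))
    return {
        "max_angle_deg": max_angle,
        "robust": max_angle < angle_limit_deg,
        "angle_limit_deg": angle_limit_deg,
        "n_subjects": len(subjects),
    }


def pm_extreme_postures(
    basis: PrincipalMovementBasis,
    pp: np.ndarray,
    k: int,
    amp_factor: float = 1.0,
    height_m: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Postures at the (amplified) extremes of one PM's score range.

    Returns the pair ``mean ± amp_factor * extreme(pp_k) * PC_k``
    de-normalized by ``height_m`` — the standard way of visualizing what
    movement a component encodes.
    """
    scores = np.asarray(pp, float)
    col = scores[:, k] if scores.ndim == 2 else scores
    lo = height_m * (basis.mean_posture + amp_factor * col.min() * basis.pc_vectors[k])
    hi = height_m * (basis.mean_posture + amp_factor * col.max() * basis.pc_vectors[k])
    return lo, hi


def pm_series_for_matrix(
    X: PostureMatrix, basis: PrincipalMovementBasis, retained: np.ndarray
) -> list[PMTimeSeries]:
    """Project every concatenated trial and differentiate its scores."""
    out = []
    for subj, cond, block in X.trial_blocks():
        pp = project(block, basis)[:, retained]
        pv, pa = differentiate(pp, X.rate_hz)
        out.append(PMTimeSeries(subj, X.groups.get(subj, ""), cond, pp, pv, pa, X.rate_hz))
    return out
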