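"""Raw marker trials -> normalized, weighted, concatenated posture matrix.

The fixed stage order is: fill gaps -> trim -> downsample -> mirror ->
select symmetric markers -> center + height-normalize -> segment-mass
weight -> concatenate.  Each row of the resulting posture matrix is one
normalized posture (84 columns for the default 28-marker set); trials
of subjects standing left-foot-in-front are mirrored about the
mediolateral axis and relabeled so every trial describes the same
stance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AXES, ML_AXIS, MarkerConfig, MarkerFrameSeries, default_marker_config, read_trial  # noqa: F401

logger = logging.getLogger(__name__)

__all__ = [
    "PostureMatrix",
    "read_trial",
    "fill_gaps_pca",
    "trim_trial",
    "downsample",
    "mirror_trial",
    "select_symmetric_markers",
    "center_and_normalize",
    "weight_markers",
    "build_input_matrix",
    "preprocess_trial",
]


@dataclass
class PostureMatrix:
    """Concatenated normalized postures with row/column bookkeeping.

    ``data``: (total frames, n_markers*3); ``row_ledger`` maps row
    ranges to (subject, condition); ``column_ledger`` maps columns to
    (marker, axis).
    """

    data: np.ndarray
    row_ledger: list[tuple[int, int, str, str]]  # (start, stop, subject, condition)
    column_ledger: list[tuple[str, str]]
    rate_hz: float
    groups: dict[str, str] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def rows_for(self, subject: str, condition: str | None = None) -> np.ndarray:
        idx = []
        for start, stop, s, c in self.row_ledger:
            if s == subject and (condition is None or c == condition):
                idx.append(np.arange(start, stop))
        if not idx:
            raise KeyError(f"no rows for subject {subject!r} condition {condition!r}")
        return np.concatenate(idx)

    def trial_blocks(self):
        """Yield (subject, condition, data block) per concatenated trial."""
        for start, stop, s, c in self.row_ledger:
            yield s, c, self.data[start:stop]


def fill_gaps_pca(
    trial: MarkerFrameSeries,
    n_components: int = 5,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> MarkerFrameSeries:
    """Impute missing marker samples by iterative low-rank reconstruction.

    Missing entries are initialized by per-column linear interpolation in
    time, then refined by alternating a truncated SVD of the (temporally
    centered) coordinate matrix with re-imputation of the missing cells
    from the rank-``n_components`` reconstruction, until the RMS change
    of the imputed values drops below ``tol`` or ``max_iter`` is hit.
    Observed entries are never modified.
    """
    X = trial.coords
    miss = np.isnan(X)
    if not miss.any():
        return trial.copy_with()
    fully_missing = miss.all(axis=0)
    if fully_missing.any():
        bad = sorted({trial.marker_labels[j // 3] for j in np.flatnonzero(fully_missing)})
        raise ValueError(f"marker(s) missing for the entire trial: {bad}")
    frac = miss.mean()
    if frac >= 0.5:
        raise ValueError(f"gap fraction {frac:.1%} exceeds 50%; refusing to impute")

    n = X.shape[0]
    t = np.arange(n)
    filled = X.copy()
    for j in np.flatnonzero(miss.any(axis=0)):
        obs = ~miss[:, j]
        filled[~obs, j] = np.interp(t[~obs], t[obs], X[obs, j])

    for _ in range(max_iter):
        mu = filled.mean(axis=0)
        U, s, Vt = np.linalg.svd(filled - mu, full_matrices=False)
        k = min(n_components, s.size)
        recon = (U[:, :k] * s[:k]) @ Vt[:k] + mu
        new = np.where(miss, recon, X)
        delta = np.sqrt(np.mean((new[miss] - filled[miss]) ** 2))
        filled = new
        if delta < tol:
            break
    logger.info("fill_gaps_pca: imputed %.2f%% of entries", 100 * frac)
    return trial.copy_with(coords=filled)


def trim_trial(trial: MarkerFrameSeries, cut_s: float = 10.0) -> MarkerFrameSeries:
    """Drop the first and last ``cut_s`` seconds (start-up and end effects)."""
    n_cut = int(round(cut_s * trial.rate_hz))
    if trial.n_frames <= 2 * n_cut:
        raise ValueError(
            f"trial of {trial.duration_s:.1f}s too short to trim {cut_s}s from both ends"
        )
    stop = trial.n_frames - n_cut
    return trial.copy_with(coords=trial.coords[n_cut:stop])


def downsample(trial: MarkerFrameSeries, target_rate: float = 120.0) -> MarkerFrameSeries:
    """Keep every (rate/target_rate)-th frame starting at frame 0."""
    ratio = trial.rate_hz / target_rate
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"sampling rate {trial.rate_hz} Hz not an integer multiple of {target_rate} Hz"
        )
    step = int(round(ratio))
    if step == 1:
        return trial.copy_with()
    return trial.copy_with(coords=trial.coords[::step], rate_hz=target_rate)


def _bilateral_pairs(labels: list[str]) -> dict[str, str]:
    """Map each L*/R* label to its contralateral partner; error if unpaired."""
    pairs: dict[str, str] = {}
    for lab in labels:
        if lab[:1] == "L":
            partner = "R" + lab[1:]
            if partner not in labels:
                raise ValueError(f"bilateral marker {lab!r} has no partner {partner!r}")
            pairs[lab] = partner
            pairs[partner] = lab
        elif lab[:1] == "R":
            partner = "L" + lab[1:]
            if partner not in labels:
                raise ValueError(f"bilateral marker {lab!r} has no partner {partner!r}")
    return pairs


def mirror_trial(trial: MarkerFrameSeries, force: bool = False) -> MarkerFrameSeries:
    """Mirror left-foot-in-front trials so all trials share the same stance.

    Negates the mediolateral axis for every marker and swaps Left/Right
    marker labels (midline markers map to themselves).  Applied only
    when ``meta.front_foot == 'left'`` unless ``force`` is set; applying
    it twice restores the original coordinates.
    """
    if trial.meta.front_foot == "right" and not force:
        return trial.copy_with()
    pairs = _bilateral_pairs(trial.marker_labels)
    coords = trial.coords.copy()
    coords[:, ML_AXIS::3] = -coords[:, ML_AXIS::3]
    out = np.empty_like(coords)
    for i, lab in enumerate(trial.marker_labels):
        src = pairs.get(lab, lab)
        j = trial.marker_labels.index(src)
        out[:, 3 * i : 3 * i + 3] = coords[:, 3 * j : 3 * j + 3]
    new_meta = trial.meta
    if trial.meta.front_foot == "left":
        from dataclasses import replace as _rep

        new_meta = _rep(trial.meta, front_foot="right")
    return trial.copy_with(coords=out, meta=new_meta)


def select_symmetric_markers(trial: MarkerFrameSeries, keep: list[str]) -> MarkerFrameSeries:
    """Retain only the bilaterally symmetric marker subset, in ``keep`` order."""
    missing = [m for m in keep if m not in trial.marker_labels]
    if missing:
        raise ValueError(f"keep-list markers absent from trial: {missing}")
    cols = np.concatenate([np.arange(3) + 3 * trial.marker_labels.index(m) for m in keep])
    return trial.copy_with(coords=trial.coords[:, cols], marker_labels=list(keep))


def center_and_normalize(trial: MarkerFrameSeries) -> np.ndarray:
    """Subtract the trial's mean posture and divide by subject height.

    Returns the dimensionless normalized coordinate block (every column
    has zero temporal mean), removing anthropometric offset and scale.
    """
    h = trial.meta.height_m
    if h <= 0:
        raise ValueError("height must be positive")
    X = trial.coords
    if np.isnan(X).any():
        raise ValueError("centering requires gap-free data; run fill_gaps_pca first")
    return (X - X.mean(axis=0)) / h


def weight_markers(
    block: np.ndarray, labels: list[str], masses: MarkerConfig | dict[str, float]
) -> np.ndarray:
    """Scale each marker's three columns by its relative segment mass."""
    if isinstance(masses, MarkerConfig):
        w = masses.normalized_weights(labels)
    else:
        missing = [m for m in labels if m not in masses]
        if missing:
            raise KeyError(f"no segment-mass weight for marker(s): {missing}")
        w = np.array([masses[m] for m in labels], float)
        w = w / w.sum()
    if block.shape[1] != 3 * len(labels):
        raise ValueError("block width inconsistent with label count")
    return block * np.repeat(w, 3)[None, :]


def build_input_matrix(
    trials: list[MarkerFrameSeries],
    blocks: list[np.ndarray],
) -> PostureMatrix:
    """Concatenate per-trial normalized blocks into one posture matrix."""
    if not trials:
        raise ValueError("no trials to concatenate")
    labels0 = trials[0].marker_labels
    rate0 = trials[0].rate_hz
    for tr in trials[1:]:
        if tr.marker_labels != labels0:
            raise ValueError(
                f"inconsistent marker sets: trial {tr.meta.subject_id}/{tr.meta.condition}"
            )
        if tr.rate_hz != rate0:
            raise ValueError("all trials must share the sampling rate")
    row_ledger = []
    start = 0
    for tr, b in zip(trials, blocks):
        stop = start + b.shape[0]
        row_ledger.append((start, stop, tr.meta.subject_id, tr.meta.condition))
        start = stop
    data = np.vstack(blocks)
    col_ledger = [(m, a) for m in labels0 for a in AXES]
    groups = {tr.meta.subject_id: tr.meta.group for tr in trials}
    logger.info("input matrix: %d rows x %d columns (%d trials)", data.shape[0], data.shape[1], len(trials))
    return PostureMatrix(data, row_ledger, col_ledger, rate0, groups)


def preprocess_trial(
    trial: MarkerFrameSeries,
    config: MarkerConfig | None = None,
    cut_s: float = 10.0,
    target_rate: float = 120.0,
    gap_components: int = 5,
) -> tuple[MarkerFrameSeries, np.ndarray]:
    """Run the full per-trial chain; returns (processed trial, weighted block)."""
    config = config or default_marker_config()
    if np.isnan(trial.coords).any():
        trial = fill_gaps_pca(trial, n_components=gap_components)
    trial = trim_trial(trial, cut_s=cut_s)
    trial = downsample(trial, target_rate=target_rate)
    trial = mirror_trial(trial)
    keep = [m for m in config.symmetric_keep if m in trial.marker_labels]
    if len(keep) == len(config.symmetric_keep):
        trial = select_symmetric_markers(trial, config.symmetric_keep)
        weights: MarkerConfig | dict[str, float] = config
    else:
        # synthetic marker sets: keep everything, uniform weights
        weights = {m: 1.0 for m in trial.marker_labels}
    block = center_and_normalize(trial)
    block = weight_markers(block, trial.marker_labels, weights)
    return trial, block


def preprocess_cohort(
    trials: list[MarkerFrameSeries],
    config: MarkerConfig | None = None,
    cut_s: float = 10.0,
    target_rate: float = 120.0,
    gap_components: int = 5,
) -> PostureMatrix:
    """Preprocess every trial and concatenate into the posture matrix."""
    processed, blocks = [], []
    for tr in trials:
        p, b = preprocess_trial(tr, config=config, cut_s=cut_s, target_rate=target_rate,
                                gap_components=gap_components)
        processed.append(p)
        blocks.append(b)
    return build_input_matrix(processed, blocks)
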