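"""Synthetic tandem-stance cohorts with known ground truth.

Real postural-sway recordings decompose into a handful of dominant
low-frequency movement components.  This module builds marker-trajectory
cohorts *backwards* from that structure: it plants an orthonormal
posture-space basis with a chosen eigenvalue profile, synthesizes one
score series per movement component whose irregularity is set by a
single mixing knob, and maps the scores back out to lab-frame marker
coordinates.  Because every quantity the analysis pipeline estimates
(eigenvalue spectrum, per-component sample entropy ordering, condition
and group effects) is planted explicitly, the generated cohorts provide
a ground-truth test surface for every downstream stage.

Score-series model: a sum of band-limited sinusoids (random frequencies
and phases, one disjoint sub-band of 0.2-2 Hz per component so that
components stay mutually uncorrelated) mixed with 1/f-filtered Gaussian
noise.  The noise-mixing weight ``w`` in [0, 1] is the irregularity
knob: ``w = 0`` gives a nearly periodic, low-entropy signal, ``w = 1``
pure colored noise.  Dual-task condition effects act multiplicatively
on ``w`` through a per-component template ("n" = peaked at the middle
condition, "monotone", or "flat"); age-group effects are a scalar
offset on ``w``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import CONDITIONS, GROUPS, MarkerFrameSeries, TrialMeta

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "make_posture_basis",
    "simulate_pp",
    "assemble_trial",
    "generate_cohort",
]

#: condition-effect templates (zero mean over the five conditions)
EFFECT_TEMPLATES = {
    "n": np.array([0.0, 0.6, 1.0, 0.6, 0.0]),
    "monotone": np.array([-1.0, -0.5, 0.0, 0.5, 1.0]),
    "flat": np.zeros(5),
}

#: Table-1-like eigenvalue decay of a tandem stance (fractions of total variance)
DEFAULT_EV_PROFILE = (0.511, 0.265, 0.097, 0.039, 0.026, 0.019)


@dataclass
class SyntheticCohortSpec:
    """Design of a synthetic cohort.

    Defaults mirror the measurement design the generator emulates:
    two age groups (23 young / 18 old), five 80 s tandem-stance trials
    per subject (single task plus four n-back dual tasks) recorded at
    240 Hz with 28 markers.
    """

    n_subjects_per_group: tuple[int, int] = (23, 18)
    n_conditions: int = 5
    n_markers: int = 28
    sampling_rate: float = 240.0
    duration_s: float = 80.0
    ev_profile: tuple[float, ...] = DEFAULT_EV_PROFILE
    #: base irregularity (noise-mixing weight) per planted component
    regularity_profile: tuple[float, ...] | None = None
    #: per-component condition-effect template name
    effect_shape: tuple[str, ...] | None = None
    #: multiplicative amplitude of the condition effect on the mixing weight
    effect_amplitude: float = 0.15
    #: additive offset on the mixing weight for the older group
    group_offset: float = 0.05
    #: total posture-space variance (dimensionless normalized-posture units^2)
    total_variance: float = 2e-4
    #: mean body height per group (m); per-subject heights drawn around these
    group_mean_height_m: tuple[float, float] = (1.70, 1.60)
    height_sd_m: float = 0.10
    noise_sd: float = 0.0
    gap_rate: float = 0.0
    #: mean occlusion run length (s) for gap generation
    gap_run_mean_s: float = 0.25
    #: spread the variance not covered by ev_profile over this many extra
    #: sub-threshold components (0 disables)
    n_residual_components: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        ev = np.asarray(self.ev_profile, float)
        if np.any(ev <= 0):
            raise ValueError("ev_profile entries must be positive")
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("ev_profile must be non-increasing")
        if ev.sum() > 1 + 1e-9:
            raise ValueError("ev_profile must sum to at most 1")
        if not 0 <= self.gap_rate < 0.2:
            raise ValueError("gap_rate must lie in [0, 0.2)")
        if self.n_conditions != len(self.condition_labels):
            raise ValueError("n_conditions inconsistent with condition labels")
        if self.regularity_profile is None:
            self.regularity_profile = tuple(0.5 for _ in ev)
        if self.effect_shape is None:
            self.effect_shape = tuple("n" for _ in ev)
        if len(self.regularity_profile) != len(ev) or len(self.effect_shape) != len(ev):
            raise ValueError("per-component profiles must match ev_profile length")
        for shape in self.effect_shape:
            if shape not in EFFECT_TEMPLATES:
                raise ValueError(f"unknown effect shape {shape!r}")

    @property
    def condition_labels(self) -> tuple[str, ...]:
        return CONDITIONS[: self.n_conditions]

    @property
    def n_pms(self) -> int:
        return len(self.ev_profile)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))

    @property
    def n_dof(self) -> int:
        return 3 * self.n_markers

    def mixing_weight(self, pm_index: int, condition: str, group: str) -> float:
        """Planted noise-mixing weight for one component/condition/group cell."""
        c = self.condition_labels.index(condition)
        tpl = EFFECT_TEMPLATES[self.effect_shape[pm_index]]
        tpl = tpl - tpl.mean()
        w = self.regularity_profile[pm_index] * (1.0 + self.effect_amplitude * tpl[c])
        if group == GROUPS[1]:
            w += self.group_offset
        return float(np.clip(w, 0.02, 0.98))


def make_posture_basis(
    n_dof: int, k: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random orthonormal posture-space basis plus a mean-posture vector.

    Returns ``(basis, mean_posture)`` with ``basis`` of shape
    ``(k, n_dof)`` (rows orthonormal) and ``mean_posture`` of length
    ``n_dof`` in normalized (height-relative) units.
    """
    if k > n_dof:
        raise ValueError(f"cannot build {k} orthonormal vectors in {n_dof} dimensions")
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((n_dof, k)))
    q *= np.sign(np.diag(r))  # fix QR sign ambiguity for determinism
    mean_posture = rng.normal(0.0, 0.2, size=n_dof)
    return q.T.copy(), mean_posture


def _pm_band(pm_index: int, n_pms: int, lo: float = 0.2, hi: float = 2.0) -> tuple[float, float]:
    """Disjoint frequency sub-band for one component, with 10% guard gaps."""
    width = (hi - lo) / n_pms
    b0 = lo + pm_index * width
    return b0 + 0.1 * width, b0 + 0.9 * width


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-filtered Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_pp(
    pm_index: int,
    condition: str,
    spec: SyntheticCohortSpec,
    subject_seed: int,
    group: str = GROUPS[0],
) -> np.ndarray:
    """Synthesize one component's score (principal-position) series.

    The series mixes 3 random sinusoids from the component's frequency
    band with 1/f noise according to the planted mixing weight, and is
    rescaled so its variance equals the component's share of the total
    posture-space variance exactly.
    """
    if condition not in spec.condition_labels:
        raise ValueError(f"unknown condition {condition!r}; expected one of {spec.condition_labels}")
    c = spec.condition_labels.index(condition)
    rng = np.random.default_rng([int(subject_seed), int(pm_index), int(c)])
    n = spec.n_frames
    t = np.arange(n) / spec.sampling_rate

    target_var = spec.ev_profile[pm_index] * spec.total_variance
    if target_var == 0:
        return np.zeros(n)

    lo, hi = _pm_band(pm_index, spec.n_pms)
    freqs = rng.uniform(lo, hi, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    amps = rng.uniform(0.5, 1.0, size=3)
    sine = np.zeros(n)
    for f, ph, a in zip(freqs, phases, amps):
        sine += a * np.sin(2 * np.pi * f * t + ph)
    sine /= sine.std()

    noise = _pink_noise(n, rng)
    w = spec.mixing_weight(pm_index, condition, group)
    x = (1.0 - w) * sine + w * noise
    x -= x.mean()
    return x * np.sqrt(target_var / x.var())


def _plant_gaps(
    coords: np.ndarray, n_markers: int, gap_rate: float, run_mean_frames: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Set contiguous per-marker runs of frames to NaN (occlusion model).

    Run starts are Bernoulli with rate ``gap_rate / run_mean_frames`` per
    frame, run lengths geometric with the given mean, so the expected
    missing fraction is approximately ``gap_rate``.  A marker is never
    blanked entirely.
    """
    n = coords.shape[0]
    out = coords.copy()
    p_start = gap_rate / run_mean_frames
    for m in range(n_markers):
        starts = np.flatnonzero(rng.random(n) < p_start)
        if starts.size == 0:
            continue
        mask = np.zeros(n, bool)
        lengths = rng.geometric(1.0 / run_mean_frames, size=starts.size)
        for s, L in zip(starts, lengths):
            mask[s : s + L] = True
        if mask.all():
            mask[: n // 2] = False  # keep the marker observable
        out[mask, 3 * m : 3 * m + 3] = np.nan
    return out


def assemble_trial(
    basis: np.ndarray,
    mean_posture: np.ndarray,
    pp_matrix: np.ndarray,
    height_m: float,
    noise_sd: float = 0.0,
    gap_rate: float = 0.0,
    seed: int = 0,
    rate_hz: float = 240.0,
    meta: TrialMeta | None = None,
    gap_run_mean_s: float = 0.25,
    marker_labels: Sequence[str] | None = None,
) -> MarkerFrameSeries:
    """Map planted score series back out to lab-frame marker coordinates.

    Inverts the pipeline's normalization: the normalized posture at time
    ``t`` is ``mean_posture + pp[t] @ basis`` (plus isotropic Gaussian
    measurement noise of SD ``noise_sd`` in the same units), and lab
    coordinates are that times the subject's height.  Occlusion gaps are
    planted as NaN runs.
    """
    basis = np.asarray(basis, float)
    pp_matrix = np.atleast_2d(np.asarray(pp_matrix, float))
    if not (np.isfinite(basis).all() and np.isfinite(pp_matrix).all() and np.isfinite(mean_posture).all()):
        raise ValueError("basis, mean posture and scores must be finite")
    if pp_matrix.shape[1] != basis.shape[0]:
        raise ValueError(
            f"pp_matrix has {pp_matrix.shape[1]} columns but basis has {basis.shape[0]} vectors"
        )
    n_dof = basis.shape[1]
    if n_dof % 3:
        raise ValueError("basis dimensionality must be a multiple of 3 (markers x XYZ)")
    n_markers = n_dof // 3
    rng = np.random.default_rng(seed)

    normalized = mean_posture[None, :] + pp_matrix @ basis
    if noise_sd > 0:
        normalized = normalized + rng.normal(0.0, noise_sd, size=normalized.shape)
    coords = height_m * normalized
    if gap_rate > 0:
        coords = _plant_gaps(coords, n_markers, gap_rate, gap_run_mean_s * rate_hz, rng)

    if marker_labels is None:
        marker_labels = [f"M{i:02d}" for i in range(n_markers)]
    if meta is None:
        meta = TrialMeta("S00", GROUPS[0], CONDITIONS[0], height_m)
    return MarkerFrameSeries(list(marker_labels), coords, rate_hz, meta)


@dataclass
class SyntheticCohort:
    """Generated trials plus the ground-truth ledger used to score recovery."""

    spec: SyntheticCohortSpec
    trials: list[MarkerFrameSeries]
    basis: np.ndarray
    mean_posture: np.ndarray
    #: per-component planted relative variance (renormalized ev_profile incl. residual)
    true_rel_ev: np.ndarray
    #: mixing weight per (subject, component, condition)
    true_mixing: dict[tuple[str, int, str], float]
    heights: dict[str, float] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)

    def ledger(self) -> dict:
        """JSON-serializable ground-truth summary."""
        return {
            "ev_profile": list(self.spec.ev_profile),
            "true_rel_ev": self.true_rel_ev.tolist(),
            "effect_shape": list(self.spec.effect_shape),
            "effect_amplitude": self.spec.effect_amplitude,
            "group_offset": self.spec.group_offset,
            "regularity_profile": list(self.spec.regularity_profile),
            "mixing_weights": {
                f"{s}|{k}|{c}": w for (s, k, c), w in self.true_mixing.items()
            },
            "heights_m": self.heights,
            "groups": self.groups,
            "seed": self.spec.seed,
        }


def generate_cohort(spec: SyntheticCohortSpec, marker_labels: Sequence[str] | None = None) -> SyntheticCohort:
    """Generate a full cohort: every subject x condition trial plus ground truth.

    Component scores are drawn per subject/condition with independent
    seeds spawned from ``spec.seed``; the posture basis is shared by the
    whole cohort.  Variance not covered by ``ev_profile`` is spread over
    ``n_residual_components`` extra orthogonal components with a
    geometric decay, all below the retention threshold of the analysis.
    """
    ev = np.asarray(spec.ev_profile, float)
    residual = 1.0 - ev.sum()
    n_res = spec.n_residual_components if residual > 1e-9 else 0
    if n_res:
        # geometric decay tuned so the default profile's first residual
        # component lands near 0.9% -- i.e. below the 1/84 retention
        # threshold, like the sub-threshold tail of a real tandem stance
        decay = 0.8 ** np.arange(n_res)
        res_ev = residual * decay / decay.sum()
        if res_ev[0] >= ev[-1]:
            raise ValueError("residual components would exceed the last planted EV; "
                             "increase n_residual_components")
        all_ev = np.concatenate([ev, res_ev])
    else:
        all_ev = ev
    k_total = all_ev.size
    if k_total > spec.n_dof:
        raise ValueError("more planted components than degrees of freedom")

    basis, mean_posture = make_posture_basis(spec.n_dof, k_total, spec.seed)
    root = np.random.SeedSequence(spec.seed)
    n_subj = sum(spec.n_subjects_per_group)
    subject_seeds = root.generate_state(n_subj + 1)[1:] % (2**31)

    full_spec = SyntheticCohortSpec(**{**spec.__dict__, "ev_profile": tuple(all_ev),
                                       "regularity_profile": tuple(spec.regularity_profile) + (0.5,) * n_res,
                                       "effect_shape": tuple(spec.effect_shape) + ("flat",) * n_res})

    height_rng = np.random.default_rng([spec.seed, 987654321])
    trials: list[MarkerFrameSeries] = []
    true_mixing: dict[tuple[str, int, str], float] = {}
    heights: dict[str, float] = {}
    groups: dict[str, str] = {}
    si = 0
    for g, n_g in zip(GROUPS, spec.n_subjects_per_group):
        for _ in range(n_g):
            sid = f"S{si:03d}"
            h = float(height_rng.normal(spec.group_mean_height_m[GROUPS.index(g)], spec.height_sd_m))
            h = max(h, 1.2)
            heights[sid] = h
            groups[sid] = g
            for cond in spec.condition_labels:
                pp = np.column_stack([
                    simulate_pp(k, cond, full_spec, int(subject_seeds[si]), group=g)
                    for k in range(k_total)
                ])
                for k in range(spec.n_pms):
                    true_mixing[(sid, k, cond)] = full_spec.mixing_weight(k, cond, g)
                meta = TrialMeta(sid, g, cond, h)
                trial = assemble_trial(
                    basis, mean_posture, pp, h,
                    noise_sd=spec.noise_sd, gap_rate=spec.gap_rate,
                    seed=int(subject_seeds[si]) + 7 * spec.condition_labels.index(cond),
                    rate_hz=spec.sampling_rate, meta=meta,
                    gap_run_mean_s=spec.gap_run_mean_s,
                    marker_labels=marker_labels,
                )
                trials.append(trial)
            si += 1

    return SyntheticCohort(
        spec=spec, trials=trials, basis=basis, mean_posture=mean_posture,
        true_rel_ev=all_ev / all_ev.sum(), true_mixing=true_mixing,
        heights=heights, groups=groups,
    )
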