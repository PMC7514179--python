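"""Shared fixtures: scaled-down synthetic cohorts and oracle helpers."""

import numpy as np
import pytest

from pmsway.pipeline import RunConfig, run_pipeline
from pmsway.synthetic import SyntheticCohortSpec, generate_cohort


def saen_bruteforce(x, m=2, tau=1, r_coeff=0.2):
    """Exhaustive-pair sample-entropy oracle (independent double loop).

    Templates are built with lag ``tau`` for dimensions m and m+1 over
    the common index range; pairs i<j are compared by Chebyshev distance
    against r = r_coeff * SD(x).  Returns (value, A, B).
    """
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    sd = (sum((v - mean) ** 2 for v in x) / n) ** 0.5
    r = r_coeff * sd
    N = n - m * tau
    B = A = 0
    for i in range(N):
        for j in range(i + 1, N):
            dm = max(abs(x[i + k * tau] - x[j + k * tau]) for k in range(m))
            if dm <= r:
                B += 1
                if abs(x[i + m * tau] - x[j + m * tau]) <= r:
                    A += 1
    if B == 0 or A == 0:
        return float("inf"), A, B
    import math

    return -math.log(A / B), A, B


@pytest.fixture(scope="session")
def small_spec():
    """Noise-free cohort at reduced size: 3+3 subjects, 40 s trials."""
    return SyntheticCohortSpec(
        n_subjects_per_group=(3, 3), duration_s=40.0, sampling_rate=240.0,
        noise_sd=0.0, gap_rate=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def pipeline_result(small_spec):
    cfg = RunConfig(
        synthetic=dict(n_subjects_per_group=(3, 3), duration_s=40.0, sampling_rate=240.0),
        seed=11, run_loo=True, out_dir="scratch/pytest_run",
    )
    return run_pipeline(cfg, write_outputs=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
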