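# pmsway

Principal-movement analysis of postural control.

Standing still is an active control problem: the nervous system continuously
corrects deviations of a high-dimensional body configuration. `pmsway`
implements the analysis chain used to study this in motion-capture data from
balance experiments (e.g. tandem stance under cognitive dual-tasking, with a
young and an older age group):

1. **Preprocessing** — gap filling by iterative low-rank reconstruction,
   trimming of start/end transients, downsampling, left/right mirroring so all
   trials share the same stance, reduction to a bilaterally symmetric marker
   set, mean-posture subtraction, body-height normalization and relative
   segment-mass weighting, concatenation into one posture matrix.
2. **Kinematic PCA** — each row of the posture matrix is one normalized
   posture; the eigenvectors `PC_k` of its covariance define *principal
   movements* (PM). Projecting a trial yields principal positions `PP_k(t)`;
   central differences give principal velocities `PV_k(t)` and accelerations
   `PA_k(t)`. The relative eigenvalue `EV_k` is the variance fraction a PM
   explains; PMs with `EV_k > 1/n_columns` (1.2% for 84 columns) are retained,
   and their robustness is screened by leave-one-subject-out refits (< 15°
   eigenvector rotation).
3. **Control measures** — per trial and PM, after zero-phase 6th-order
   Butterworth low-pass filtering at 7 Hz:
   `SaEn^PP` (sample entropy of the detrended `PP`, sway irregularity),
   `SaEn^PA` (sample entropy of `PA`, irregularity of the control signal),
   `N` (number of `PA` zero crossings — corrective interventions), and
   `σ` (SD of the time between crossings — intervention-timing variability).
   Sample entropy uses `m = 2`, `r = 0.2·SD`, and a delayed embedding with lag
   `τ = 12` samples (100 ms at 120 Hz).
4. **Statistics** — a split-plot repeated-measures ANOVA per variable and PM
   (within factor: dual-task condition; between factor: age group), with
   Mauchly's sphericity test, Greenhouse–Geisser/Huynh–Feldt corrections
   (GG when ε_GG < 0.75, HF otherwise), partial eta squared, observed power
   from the noncentral F distribution, and Sidak-corrected pairwise post-hocs.
5. **Synthetic cohorts** — `pmsway.synthetic` generates marker trials
   *backwards* from a planted orthonormal posture basis, a chosen eigenvalue
   profile, and per-component score signals whose irregularity is set by a
   noise-mixing knob, with condition ("n"-shaped, monotone, flat) and group
   effects planted on that knob. Every quantity the pipeline estimates has a
   ground-truth ledger entry, so the full chain is testable without access to
   laboratory recordings.

## Worked example

```python
from pmsway import RunConfig, run_pipeline

cfg = RunConfig(
    synthetic=dict(n_subjects_per_group=(6, 6), duration_s=60.0,
                   sampling_rate=240.0),
    seed=1, out_dir="out")
res = run_pipeline(cfg)

print("retained PMs:", [int(i) + 1 for i in res.retained])
print("EV [%]:", res.basis.rel_ev_pct[:6].round(2))
print("planted EV [%]:", (100 * res.cohort.true_rel_ev[:6]).round(2))
print("max LOO angle [deg]:", res.loo["max_angle_deg"].max().round(2))
```

prints

```
retained PMs: [1, 2, 3, 4, 5, 6]
EV [%]: [50.58 27.07  9.68  3.92  2.52  1.93]
planted EV [%]: [51.1 26.5  9.7  3.9  2.6  1.9]
max LOO angle [deg]: 2.02
```

i.e. the pipeline recovers the planted eigenvalue spectrum to a fraction of a
percent, and the leave-one-out validation confirms the component orientations
are stable (well under the 15° robustness limit). `res.measure_table` holds
the tidy per-trial measures and `res.effects` / `res.posthoc` the ANOVA
layer; with the default planted "n"-shaped irregularity effect, mean
`SaEn^PP` of the leading PMs peaks in the middle dual-task condition (~10%
above single task).

The same analyses run from a shell:

```bash
pmsway simulate --config cfg.yaml --seed 1 --out trials/
pmsway pma trials/*.csv --out out/
pmsway run-all --config cfg.yaml --seed 1 --out out/
pmsway stats out/measures.csv --out out/
```

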