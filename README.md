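# fearpet

Quantification of task-induced dopamine release from a **single-scan
bolus-infusion [¹¹C]raclopride PET** experiment, built around the **nested
two-step simplified reference tissue model (SRTM)**, together with the
skin-conductance learning index and the subject-level statistics used in
fear-conditioning release studies. Everything runs on synthetic data
produced by the package's own generators, so the method, its validation
study and the cohort-level analysis are fully reproducible on a laptop.

## Who this is for

PET methodologists and cognitive-neuroscience groups who want a tested,
scriptable implementation of the single-scan release measurement: simulate
realistic bolus-infusion time-activity curves (TACs), fit them, characterise
bias and precision per binding regime, and run the complete
release × learning correlation analysis on simulated cohorts.

## The model

The SRTM expresses a target-region TAC as a function of the reference-region
TAC C_R and three parameters,

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·[C_R ⊗ e^(−k2a t)](t),

with k2 = R1·k2′ the target efflux, k2a = k2/(1 + BP_ND) the apparent
efflux, R1 the relative delivery and BP_ND the non-displaceable binding
potential. For a challenge delivered mid-scan the **nested two-step** fit

1. fits (R1, k2′, BP_ND) to the pre-challenge 0–50 min frames (basis-function
   or direct nonlinear least squares), then
2. refits **only** the post-challenge binding potential BP′_ND on the
   70–90 min frames with R1 and k2′ fixed,

and reports dopamine release as **100 × (1 − BP′_ND / BP_ND)**. The
synthetic generator drives a two-tissue-compartment system (one-tissue
reference) with a plasma bolus + constant-infusion input (kbol 107 min),
implements release as a linear reduction of k3 between 50 and 70 min, and
adds pseudo-Poisson frame noise (SD ∝ √(C/Δt)). SCR trial tables are
floored at 0.01 µS, square-root transformed, range-corrected to each
subject's maximum, and summarised as the CS+ − CS− learning delta. Cohort
inference uses directed paired t-tests, directed Pearson correlations with
one-sided intervals, a Mahalanobis outlier screen against χ²(2) at
P < 0.001, and Steiger's Z for dependent correlations.

## Worked example

```python
import numpy as np
from fearpet import (FrameSchedule, InputModel, TissueParams, ReleaseSchedule,
                     NoiseModel, DEFAULT_KINETICS, simulate_tissue_tac,
                     add_noise, fit_srtm_baseline, fit_post_challenge)

frames = FrameSchedule.default()            # 18 x 5 min, 0-90 min
plasma = InputModel()                       # bolus-infusion, kbol 107 min
amygdala = TissueParams(BP_base=0.3, **DEFAULT_KINETICS)
reference = TissueParams(**DEFAULT_KINETICS)
release = ReleaseSchedule(mode="linear_ramp", drop_fraction=0.15)

tac, ref = simulate_tissue_tac(plasma, [amygdala, reference],
                               [release, None], frames)
rng = np.random.default_rng(7)
tac = add_noise(tac, frames, NoiseModel(), rng)
ref = add_noise(ref, frames, NoiseModel(), rng)

fit = fit_srtm_baseline(tac, ref, frames)           # step 1: 0-50 min
nested = fit_post_challenge(tac, ref, frames, fit)  # step 2: 70-90 min
print(f"BP_ND = {fit.params.BP_ND:.3f}, BP'_ND = {nested.bp_post:.3f}, "
      f"release = {nested.release_percent:.1f}%")
```

prints

```
BP_ND = 0.333, BP'_ND = 0.270, release = 19.2%
```

i.e. the baseline fit recovers a binding potential near the simulated 0.3,
the post-challenge refit tracks the reduced binding, and the release
estimate lands near the simulated 15% (the deviation reflects frame noise
at the default level, which gives the estimate a COV near 10% in this
binding regime).

The same steps are available from the shell:

```bash
fearpet simulate --bp 0.3 --release 15 --seed 7 --out tac.tsv --ref-out ref.tsv
fearpet release tac.tsv --reference ref.tsv
fearpet simstudy --replicates 100 --seed 1 --out-dir study/
fearpet cohort --n 18 --seed 1 --out-dir cohort/
```

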