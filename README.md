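# intralobe

Simulation and analysis toolkit for **within-patient lobe-randomized
radionuclide-uptake trials** in neuroendocrine liver metastases.

In this trial design every patient carries both arms: one liver lobe is
randomized to receive the radiopharmaceutical (e.g.
[¹⁷⁷Lu]Lu-DOTATATE) **intra-arterially** through its hepatic artery, while
the metastases in the contralateral lobe are exposed through the systemic
circulation and serve as the within-patient control. The endpoint is the
tumour-to-non-tumour uptake ratio on post-treatment SPECT/CT,

```
T/N = (Σᵢ vᵢ·ūᵢ / Σᵢ vᵢ) / ū_normal
```

the volume-weighted mean counts per voxel over the target-lesion VOIs
divided by the mean counts in a ≥15 mL healthy-liver VOI in the control
lobe, computed per lobe (T/N_IA and T/N_control) and compared within
patients by a paired *t*-test, a paired *t*-test on log T/N (back-
transformed to a geometric ratio), and — across treatment cycles — a
linear mixed model with random intercepts per patient and per cycle within
patient.

Because patient imaging of this kind is not publicly available, the
package ships a phantom generator that reproduces the statistical
structure of such a trial (bilobar liver, 1–3 spherical lesions ≥ 30 mm per
lobe, Poisson count noise, a lobe-selective multiplicative enhancement ρ,
rigid baseline-to-cycle misalignment, follow-up diameters and laboratory
panels), so the entire chain — segmentation, VOI transfer, uptake
extraction, inference, RECIST 1.1 response, CTCAE-style toxicity — is
testable end to end.

## What is implemented

| module | contents |
| --- | --- |
| `intralobe.synthetic` | phantom/cohort generator (`CohortConfig`, `build_phantom`, `generate_cohort`, follow-up, labs, tabular T/N simulators) |
| `intralobe.quant` | 42 %-of-max lesion VOI segmentation, rigid VOI transfer, mean uptake, 1 cm-sphere peak uptake, the T/N statistic |
| `intralobe.design` | permuted-block (sizes 1 and 2) in-patient randomization; exact noncentral-*t* paired power and minimum sample size |
| `intralobe.stats` | paired *t*, log-ratio test, two-level random-intercept LMM, covariate effect-modification tests, exact Fisher r×c, increase proportion |
| `intralobe.response` | RECIST 1.1 per-lobe classifier, configurable CTCAE-style lab grading, baseline-delta toxicity attribution |
| `intralobe.pipeline` / `intralobe.cli` | end-to-end orchestration and the `intralobe` command |

## Worked example

Run the full chain on a synthetic 27-patient cohort (4 cycles, default
calibration: geometric mean control T/N 16.2, enhancement ρ with geometric
mean 1.17):

```bash
intralobe report --seed 7 --outdir run
```

prints (and writes to `run/report.txt`):

```
seed=7  config=c6cb1b9bb3d73844
[mean] cycle 1: mean difference 2.38 (95% CI [-0.38, 5.14], p=0.088); geometric ratio 1.097 (95% CI [0.966, 1.246], p=0.148); 15/27 increased
[mean] all cycles LMM: arm effect 2.367 (95% CI [1.387, 3.347], p=0.000)
[peak] cycle 1: mean difference 1.73 (95% CI [-1.24, 4.70], p=0.243); geometric ratio 1.064 (95% CI [0.890, 1.273], p=0.480); 16/27 increased
[peak] all cycles LMM: arm effect 2.525 (95% CI [1.083, 3.968], p=0.001)
response 3mo: Fisher exact p=0.035
response 6mo: Fisher exact p=0.093
treatment-emergent lab toxicities: 69
```

Reading the first line: on this simulated cohort the treated-lobe T/N
exceeded the control-lobe T/N by 2.38 on average (not significant at the
5 % level), the within-patient geometric ratio was 1.097 (i.e. +9.7 %,
sampling noise around the configured +17 %), and 15 of 27 patients showed
any increase. `run/` also contains the per-cycle T/N table
(`tn_ratios.csv`), the randomization list, response tables with Fisher
p-values, and the toxicity grade table as CSV files.

Other verbs: `intralobe generate` persists the cohort as NIfTI volumes and
CSV manifests; `intralobe randomize --n 27 --seed 1` prints a permuted-
block sequence; `intralobe power --dz 0.65` prints
`{"min_n": 27, "power": 0.9015...}` — the exact two-sided noncentral-*t*
answer at the design effect size d_z = 0.65 and 90 % power.

As a library:

```python
import intralobe as il

cfg = il.CohortConfig(n_patients=27, seed=1)
phantom = il.build_phantom(cfg, patient_seed=7, ia_lobe="right")
voi = il.segment_lesion_voi(phantom.baseline_volume,
                            phantom.rough_voi(phantom.lesions[0].lesion_id))
il.mean_uptake(phantom.cycle_volumes[0], voi)
```

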