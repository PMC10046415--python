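# thermowave

Physics-assisted deep-learning microwave imaging for **non-invasive
temperature monitoring during hyperthermia treatment (HT)** of neck tumors —
an in-silico testbed.

During HT the tumor must reach the therapeutic range (ΔT ≈ 3–7 °C above the
37 °C baseline) while nearby heat-sensitive tissue — here the spinal cord —
must stay unheated. Tissue dielectric properties drift with temperature, so
the tiny changes they imprint on microwave scattering data carry the thermal
state of the anatomy. `thermowave` simulates the entire monitoring chain on
a synthetic 2D neck phantom and quantifies how well it classifies the
thermal status of both regions of interest (ROIs):

1. **Tissue dielectrics** — two-pole Cole–Cole dispersion per tissue,
   εr(ω,T) = ε∞ + Δε₁/(1+(jωτ₁)^{1−α₁}) + Δε₂/(1+(jωτ₂)^{1−α₂}) + σ/(jωε₀),
   with linear relative temperature rates on the tumor and cord parameters.
2. **Forward scattering** — scalar 2D TM volume integral equations (state
   and data equations) solved by a pulse-basis/point-matching method of
   moments over a 12-antenna multistatic ring at 10 frequencies in
   0.9–1.8 GHz; 30 dB AWGN on both measurement sessions.
3. **Differential imaging** — the distorted-wave Born approximation (DWBA)
   linearizes the problem around the pre-heating baseline, whose total
   field E_tot⁰ plays the role of the Green's function:
   ΔE_S = k_b² ∫ E_tot⁰(r′,r_m) E_tot⁰(r′,r_v) δχ(r′) dr′. Restricted to
   each ROI window and inverted by truncated SVD,
   δχ = Σ_{p≤P_cut} λ_p⁻¹ (u_pᴴ ΔE_S) ν_p, with P_cut = 1.
4. **Classification** — each ROI image (Re/Im channels of δχ) is labelled
   from the imposed ΔT (tumor: unheated/therapeutic/hot at 3 and 7 °C;
   cord: unheated/hot at 2 °C) and classified by a compact CNN trained with
   Adam (lr 10⁻⁴, batch 16, ≤300 epochs, early stopping) under 10-fold
   cross-validation.
5. **Metrics** — per-class Dice similarity coefficient
   DSC = 2TP/(2TP+FP+FN) and Matthews correlation coefficient
   MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), fold-averaged,
   plus confusion matrices and misclassification rates.

Everything is generated internally; there are no external data
dependencies. All randomness is seeded and runs are bit-reproducible.

## Worked example

```python
from thermowave import RunConfig, run_experiment, report

cfg = RunConfig.from_preset("reduced", seed=1)   # 64x64 grid, desk scale
result = run_experiment(cfg)
print(report(result))
```

prints (abridged; ~6 minutes on one CPU):

```
Tumor CNN (fold-averaged, validation splits)
  class            DSC     MCC
  unheated       0.893   0.846
  therapeutic    0.799   0.680
  hot            0.859   0.803
  misclassified: 59/400 (14.8%), accuracy 85.2%

Spinal cord CNN (fold-averaged, validation splits)
  class            DSC     MCC
  unheated       0.866   0.708
  hot            0.839   0.708
  misclassified: 43/300 (14.3%), accuracy 85.7%
```

Each row is the fold-averaged one-vs-rest score of that thermal class on
the held-out validation splits; the confusion-matrix breakdown (written by
`report`) shows that essentially all errors sit one class across the 3 °C
and 7 °C (tumor) or 2 °C (cord) boundaries — the physically ambiguous
samples. The `full` preset reproduces the complete study conditions
(128×128 grid, N = 3000/2000 samples) and takes several CPU-hours.

There is also a CLI:

```sh
thermowave replicate --preset reduced --seed 1 --out runs/demo
thermowave simulate  --preset reduced --seed 1 --out runs/data
```

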