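# Methods

## Scope and model

`thermowave` is an in-silico testbed for microwave-thermometry monitoring of
neck-tumor hyperthermia. The treated slice is modelled as a 2D problem: all
tissues are assumed invariant along the body axis and are probed in TM
polarization under the e^{jωt} convention, which reduces Maxwell's equations
to a scalar problem in the longitudinal electric field. The monitoring
chain is: forward scattering simulation → differential (DWBA) imaging of
two regions of interest → CNN classification of each ROI's thermal status.

Temperatures are **imposed** on the tumor and spinal-cord pixels directly;
no applicator field, SAR, or bio-heat modelling is performed. The baseline
(pre-heating) anatomy is assumed perfectly known, emulating the tissue
segmentation produced by the MR treatment-planning stage; a config switch
(`SimulationSetup.nominal_baseline`) builds the imaging operator from the
nominal rather than the sample's own randomized phantom to study model
mismatch.

## Tissue dielectrics

Each tissue follows a two-pole Cole–Cole dispersion plus a conductivity
term (parameters ε∞, Δε₁, Δε₂, τ₁, τ₂, α₁, α₂, σ at 37 °C). The bundled
table (`data/tissue_table.json`) holds synthetic, representative values
chosen to give realistic permittivity/conductivity in the 0.5–2.5 GHz band
for skin, fat, muscle, cortical bone, spinal cord, thyroid, and a nodular
thyroid tumor (elevated permittivity and conductivity relative to healthy
thyroid); it is fixture data, not a transcription of a published database.
The vacuum permittivity is the CODATA value 8.8541878128×10⁻¹² F/m
(configurable for bit-matching against sources that round it).

Temperature enters as a per-parameter linear relative rate referenced to
37 °C, p(T) = p·(1 + c_p·(T − 37)), applied only to the heat-bearing
structures (tumor, spinal cord) over the validity window [37, 46] °C.
Defaults: c_σ = +2 %/°C, c_Δε₁ = −0.5 %/°C, all others zero — the upper
end of the range reported for soft tissues at ~1 GHz. At the band center
this puts the tumor's differential contrast at |δχ| ≈ 0.04 for ΔT = 3 °C
and ≈ 0.12 for ΔT = 9 °C. All coefficients are exposed in the tissue table.

## Phantom

The default imaging domain is a 24×24 cm square, 128×128 cells (1.875 mm).
The neck is an ellipse (semi-axes 5.5×5.0 cm) with 2 mm skin and 3 mm fat
shells over muscle; a 1.8 cm vertebra disc with a 5 mm-radius spinal cord
sits posteriorly, two 9 mm thyroid lobes anteriorly, and a 4.5 mm-radius
tumor disc is embedded in one lobe. The domain side was chosen so the
tumor (9 mm diameter) fits the 5×5-pixel tumor crop and the cord the
6×6-pixel crop — the crops are windows around the structures, so cell size
and structure size fix the domain scale.

Per-sample variability emulates patient-to-patient and session-to-session
dielectric uncertainty: for every tissue independently, Gaussian offsets
with sd 0.1 are added to the real and the loss part of the
frequency-evaluated complex permittivity, constant across the band
(optionally clipped at ±0.2, off by default; perturbing the Cole–Cole
parameters instead would be an alternative reading and is not implemented
as the default). Labels are never changed by randomization.

## Forward solver

The state equation is discretized with pulse basis functions and point
matching on the raster (Richmond cells): each square cell is replaced by
the equal-area disc, over which the 2D Green's function
g = (−j/4)H₀⁽²⁾(k_b R) integrates in closed form; the singular self term is
integrated analytically. Antennas are 12 co-located point (line) sources
on a 9 cm ring — two groups of three flanking the anterior applicator gap
at ±45°, six over the posterior arc [120°, 240°] — and the background is a
lossy water-mixture coupling medium (εr′ = 23, σ = 1.0 S/m by default;
alternatives with higher permittivity were measured to give slightly worse
differential-signal SNR and the default was kept). Grids ≤64² use a dense
LU solve; larger grids use an FFT-accelerated iterative solve (lgmres,
relative residual 10⁻⁶) exploiting the convolutional kernel structure. A
warning is raised below 10 cells per background wavelength.

Validation is two-route: an independent cylindrical-harmonic series for TM
scattering by a homogeneous circular cylinder under line-source incidence
(summed to 10⁻¹² relative truncation) agrees with the MoM receiver data to
<2% relative RMS at the default discretization, and the multistatic data
matrix is reciprocal to machine precision for co-located arrays.

Measurement noise is complex circular AWGN scaled per frequency block so
total signal power / noise power = 10^(SNR/10), SNR = 30 dB, drawn
independently for the baseline and in-treatment measurement sessions (so
the differential data carries both draws).

## Differential imaging

Because HT-range property changes are small (|δχ| ≪ |χ|), the problem is
linearized around the baseline state (distorted-wave Born approximation):
the baseline total field plays the role of the Green's function, and the
row of the ROI operator for (frequency, receiver m, transmitter v) is
k_b²·E_tot⁰(r_p, r_m)·E_tot⁰(r_p, r_v)·(cell area) over the window pixels
r_p, with receiver-side fields obtained by reciprocity. Per-frequency
blocks are stacked unweighted into one system before a single SVD —
noise-whitened (per-frequency normalized) stacking was measured at
+0.9 dB for the cord but −0.9 dB for the tumor coefficient SNR, so the
plain stacking is the default. The SVD is computed once per baseline state
(offline); each inversion is then O(P_cut·N_f·N_m·N_v). Default
P_cut = 1: with one retained triplet the image is rank-one and the
informative statistic is the complex coefficient u₁ᴴΔE_S/λ₁.

## Classification

Tumor classes from ΔT: unheated (<3 °C), therapeutic ([3,7) °C), hot
(≥7 °C); cord: unheated (<2 °C), hot (≥2 °C). Temperatures are drawn
uniformly on the discrete 1 °C grids [37..46] (tumor) and [37..40] (cord),
independently, so one simulation feeds both datasets.

The two CNNs share the architecture conv(3×3,16)→ReLU→conv(3×3,32)→ReLU→
dense(64)→ReLU→dense(N_c)+softmax (~56k parameters at the 5×5 input; the
layer sizes are configuration values chosen to keep the parameter count
well below the dataset sizes). Training: Adam, lr 10⁻⁴, batch 16, ≤300
epochs, early stopping
after 10 epochs without validation-loss improvement with best-validation
weights restored, per-fold re-initialization with fold-indexed seeds.
The categorical cross-entropy is normalized by N·N_c by default (a
`per_class_normalized_loss=False` flag gives the conventional 1/N; the
gradient direction is identical up to scale). Inputs are not standardized
by default — δχ magnitudes are physically meaningful — with an optional
per-channel scaling flag. 10-fold cross-validation partitions a seeded
permutation into equal contiguous folds; every sample is validated exactly
once. Metrics (one-vs-rest DSC and MCC per class) are computed on each
fold's validation split and averaged arithmetically; confusion matrices
are summed.

## Scale presets and desk scaling

* `full`: 128×128 grid, 10 frequencies, N = 3000 (tumor) / 2000 (cord),
  fold validation splits of 300/200. Several CPU-hours.
* `reduced`: 64×64 grid, 10 frequencies, N = 400/300 (~6 min one CPU);
  this is what the tests and `scripts/acceptance.py` run.

Two desk-scaling choices matter and were fixed by measurement:

1. **ROI crops scale physically, not in pixels.** The 5×5/6×6-pixel crops
   correspond to ~9–11 mm windows at full resolution. At 64² the same
   pixel counts would span 19–23 mm; the first singular vector of the ROI
   operator then concentrates away from the 9 mm tumor and captures only
   ~30% of the differential-signal energy (vs ~75% for a physically tight
   window), destroying class separability. The reduced preset therefore
   uses 3×3 crops (11.25 mm — the same physical extent), and the CNN input
   becomes (3,3,2).
2. **The full 10-frequency band is kept.** Frequency diversity contributes
   ~5 dB of coefficient SNR at the decisive ΔT = 3 °C boundary and is
   cheap at 64²; with 3 frequencies the task degrades to ~66% accuracy.

Finer grids (80², 96²) were measured to give no additional coefficient SNR
at ~30× the cost, so 64² is the desk-scale operating point.

## What passing tests do and do not show

The generator emulates dispersive, temperature-sensitive tissues,
anatomical layering, per-sample dielectric variability, and measurement
noise. It does not emulate: real anatomical geometry (the synthetic
ellipse-and-discs neck stands in for a segmented anatomical slice),
realistic antenna feeds or mutual coupling, 3D propagation, motion, or a
physical temperature field (uniform imposed ROI temperatures). Monitoring
metrics obtained with a real anatomical model and a measured
temperature-dependence model are therefore reproduced only approximately:
at desk scale this implementation reaches ~85% validation accuracy for
both classifiers, with errors confined to the one-degree neighbourhoods of
the class boundaries, and the information ceiling of the rank-one Pcut=1
images (measured with a multinomial logistic probe) sits at the same
level — the residual gap to headline values in the ~92% range traces to
the stand-in tissue/temperature parameters and the independent two-session
noise, not to the inversion or the training.

## Numerical choices

* Fractional Cole–Cole exponents on the principal branch; εr″ clamped at 0.
* Background wavenumber on the branch with Im(k_b) ≤ 0 (decaying outgoing
  waves under e^{jωt}).
* TSVD excludes triplets below 10⁻¹² of λ₁ (numerical null space) with a
  warning; P_cut outside [1, rank] is an error.
* MCC returns 0 (with a warning) when a marginal is zero; DSC is NaN when
  its denominator vanishes; fold averaging uses nanmean.
* Degenerate inputs (zero tumor radius, structures that do not fit their
  crops, antennas inside the neck, non-increasing frequency lists,
  out-of-window temperatures, negative ΔT) raise immediately.
* Simulation failures skip the sample with a logged reason; more than 1%
  skips aborts the run. All seeds derive from one `SeedSequence` root.
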