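# Methods

This note documents the models behind `platelab`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical design choices. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Spreading model and morphometry

### Generator

Each synthetic platelet is an ellipse rasterized on a 0.1 µm/px grid
(pixel-centre-inside rule) whose area follows a logistic law

    A(t) = A0 + (Af − A0) / (1 + exp(−(t − t_half)/τ)).

The aspect ratio relaxes from `aspect0` (1.3) to a per-platelet final
value (log-normal, median 1.05) with a 5-min timescale; the minor axis
follows from area and aspect and is clipped at the line width (4 µm)
for confined platelets, with the major axis then set to preserve the
analytic area. The orientation relaxes exponentially (4-min timescale)
toward a final angle drawn wrapped-normal (σ = 6°) around the pattern
direction for confined platelets — so the cohort sits within a ±15°
envelope — and stays at its uniform random initial value for controls.
Confined platelets are centred on a line with 0.15 µm lateral jitter.

Sequences are 161 frames at 15 s (40 min). Per-platelet log-normal
jitter (medians preserved): final area σ_log 0.15, initial area 0.15,
spreading time 0.05, final aspect 0.08.

### Calibration to the observable definitions

The analysis defines the spreading time on the *observation window*
(first/last-frame areas as 0/100 %) and reports the *final-frame* area.
Within a 40-min window these differ from the raw logistic quantities
(2 ln 3·τ and Af) by up to ~12 %, so the generator calibrates per
platelet: τ is root-solved so the windowed 25–75 % interval equals the
drawn target (15 min confined / 8.7 min control median), and the
asymptote Af is set so A(40 min) equals the drawn final area (median
30 µm²). This keeps the generator/analyzer contract exact: every
ground-truth value has the definition the analysis computes.

Two feasibility guards follow from the same window: `t_half` moves
earlier when needed to keep `duration ≥ t_half + 3τ`, and τ is capped at
the boundary (≈12.1 min, i.e. a ≈15.6-min measured interval) beyond
which a logistic in a 40-min window can no longer double its observed
first-frame area — the criterion that defines a spreading platelet.
The cap truncates only the slow tail of confined draws and leaves the
cohort median at 15 min.

Note that the printed condition medians are mutually constraining under
an ellipse model: a 4-µm minor axis and a 30 µm² area force a confined
aspect ratio of 4A/(πw²) ≈ 2.39, so the fold change over a near-round
control (median aspect 1.05) is ≈2.2–2.3 rather than exactly 2.5; the
control aspect was chosen near 1 for precisely this consistency reason.

### Measurement

Shape is measured by the area-matched moment ellipse: second central
moments of the pixel-centre set give the orientation
`½·atan2(2µ11, µ20−µ02)` and raw semi-axes `2√λ1 ≥ 2√λ2`; both are
rescaled so the ellipse area equals pixel count × pixel-size². Area is
always the pixel count, never the ellipse. Rasterized ellipses ≥5 µm²
match the analytic area within 2 % and the axes within 3 % at 0.1 µm/px.

Tracking is greedy nearest-neighbour on centroids, accepting matches up
to `d_max` = 2 µm per 15-s frame (platelet centroids move little at this
cadence); tracks shorter than 3 frames are dropped. Crossings (t₀ and
the 25/75 % levels) use the first upward crossing with linear
interpolation — a deterministic rule for noisy traces. Nonspreading
platelets are excluded from kinetic statistics but kept in the cohort
table for auditability.

## 2. SICM forward model

At each pixel the ion current follows a hyperbolic law in the tip–sample
gap g,

    I/I_sat = g / (g + λ_c),

so the trigger (98 % of saturation) corresponds to g₉₈ = 49 λ_c and the
99 % level to g₉₉ = 99 λ_c. The applied pressure P indents the sample
by

    w(g) = w_max · λ_P/(λ_P + g),   w_max = c_d · P · r_i / E_eff,

and thin samples on glass look stiffer through the thickness factor

    E_eff = E / φ(h),   φ(h) = h/(h + h_c) ∈ (0, 1).

For a tip at height z the gap solves `g − w(g) = z − z_surf`, a
quadratic with closed-form positive root (monotone in z). Curves are
sampled on a shared descending grid at `z_step` with i.i.d. Gaussian
current noise per sample and stop at the first sample below the
trigger, exactly as the instrument does. Two consequences are retained
deliberately and *not* corrected downstream, mirroring the real
measurement: soft pixels trigger lower by w(g₉₈) (pressure-induced
topography bias), and the stop rule truncates the curve just below the
trigger.

Constants (configurable; defaults are the package's simulator values):
r_i = 90 nm (inner tip radius), λ_c = 20 nm, λ_P = 500 nm, c_d = 1,
h_c = 100 nm, P = 10 kPa, z_step = 5 nm, noise σ = 10⁻³·I_sat,
pixel 0.4 µm, sample tilt (20, 10) nm/µm. With these, the deformation
distance between the 99 % and 98 % levels is

    dz_def = w(g₉₈) − w(g₉₉) = w_max · C_geom,
    C_geom = λ_P·(g₉₉−g₉₈) / ((λ_P+g₉₈)(λ_P+g₉₉)) ≈ 0.136,

i.e. ≈31–53 nm for E_eff in 2.3–4 kPa — resolvable at the 5-nm sampling
only by averaging (below). This closed-form pair (forward and inverse)
is a self-consistent stand-in for an instrument calibration; when
analyzing real data the constants are user-supplied calibration
parameters.

### Synthetic surfaces

Confined platelets are paraboloid caps clipped to the line (minor axis
= line width, area median 30 µm², peak 0.8 µm ⇒ mean height 0.4 µm,
volume 12 fL); their pixel-height distribution is uniform, so the
height skewness is ≈0 — the "no distinct lamellipodium" morphology.
Controls are a flat 0.4-µm lamellipodial rim with a central cos² dome
(peak 1.14 µm over 55 % of the radius ⇒ mean 0.467 µm, volume 14 fL);
flat-dominated, skewness ≈ +1.9. Moduli: 2.3 kPa (confined, with a
2× stiffened band within 0.5 µm of the line edges — the actin-rich edge
regions) and 4.2 kPa (control); substrate 10⁶ kPa. Per-platelet
log-normal jitter: area 0.12, heights 0.08, modulus 0.08 (σ_log).

The generator reports two ground truths per platelet: the *geometric*
surface statistics, and the *apparent* statistics computed from the
noiseless forward-predicted trigger topography (which includes the
retained pressure bias, ~0.34·w_max lower on soft pixels). Recovery is
assessed against the apparent truth — that is the quantity the
measurement chain defines; the geometric truth would only be reachable
by correcting the bias the pipeline intentionally leaves in.

## 3. SICM analysis chain

**Level location.** The slope between the 99 % and 98 % levels is
shallow (2·10⁻⁵–5·10⁻⁶ I_sat/nm), so locating a level by single-crossing
interpolation carries 50–200 nm of noise into a 8–120 nm signal, and the
trigger stop leaves no samples below the 98 % level at all. Levels are
therefore located by a windowed inverse regression: the transformed
current `u = I/(I_sat−I)` equals g/λ_c, and after subtracting the
(estimated) indentation term, `y = u − w(λ_c u)/λ_c = (z − z_surf)/λ_c`
is *exactly* linear in z for every pixel. y is fitted linearly over a
window (600 nm above the trigger crossing; −600/+300 nm around the 99 %
crossing) and solved for the level. Because the indentation amplitude
is initially unknown, the extraction iterates three times, re-estimating
w_max from the measured dz excess and re-centring the upper window on
the measured crossing. Two de-biasing details matter at σ = 10⁻³:
weights use the inverse-variance scaling (I_sat−I)⁴ computed from a
21-sample smoothed current (raw-sample weights are anticorrelated with
the noise and bias the fit low by tens of nm), and the convexity of the
u-transform (E[u] ≈ u + σ²/(1−I)³) is subtracted using a noise variance
estimated from far-field second differences. On noiseless curves all of
these corrections vanish and the estimator is exact: rigid dz = 50 λ_c
to <10⁻³ nm and dz_def matches the closed form to <0.01 %. On noisy
curves the per-pixel dz noise is ≈26 nm — close to the Cramér–Rao bound
(~15 nm) for joint (z_surf, w_max) estimation at this noise level, which
no per-pixel estimator can beat by much.

**Topography** uses the same regression for the trigger crossing
(initialized at the raw interpolated crossing, with which it coincides
exactly on noiseless data); this removes the early-stop bias and most of
the variance of the single-sample crossing (σ ≈ 11 nm vs ≈33 nm).

**Leveling** fits a least-squares plane to all pixels, excludes pixels
>50 nm above it, and refits until the exclusion set is stable (≤10
iterations). Because that one-sided cut truncates the right tail of the
trigger-noise distribution, the plane sits a few nm below the substrate
mean; after segmentation the zero level is therefore refined as the mean
over all unlabeled (untruncated) pixels. Leveling is idempotent to <1 nm
RMS and assumes ≥30 % substrate in the field.

**Segmentation**: height > 50 nm, 8-connected components, minimum area
2 µm². **Inversion**: `dz_def = dz − median(dz over substrate)`, floored
at `dz_floor = 2·z_step`; pixels at or below the floor are reported as
rigid/undefined rather than as absurdly stiff; `E_app = c_d·P·r_i·C_geom
/ dz_def`. Before inversion, dz is pooled over a 5×5 neighbourhood
*within* the platelet mask (normalized convolution, no substrate
dilution): the per-pixel dz noise (≈26 nm) is comparable to the
deformation signal of the stiffer condition (≈24 nm), and without
pooling the floor masks the low-dz tail asymmetrically and biases the
within-platelet median modulus by ≈−10 %. Pooling assumes the modulus
field varies smoothly on the 2-µm scale — true of the generated fields
and typical of SICM maps; sharp sub-2-µm stiffness features would be
blurred. **Correction**: `E_corr = E_app·φ(h)` on platelet pixels, h
from the leveled topography (h = h_c halves E_app exactly; h ≤ 0 is
masked). **Records**: area, median E_corr over defined pixels, the 99th
percentile of heights (linear-interpolation quantile, as all quantiles
in the package), volume = mean height × area (so volume equals the sum
of pixel heights × pixel area to machine precision), and the population
Fisher skewness of the heights (0 for constant samples by convention —
and note the sign semantics: with the flat-rim morphology, *positive*
skewness indicates a predominance of flat regions).

**Known systematics.** Because the topography bias is retained, φ is
evaluated on heights that are low by w(g₉₈), leaving the recovered
median modulus ≈3–7 % below the configured value (both conditions,
verified in the round-trip tests); volumes track the apparent truth
within ~2 % per platelet. These sit comfortably inside the ±10 % / ±5 %
round-trip tolerances but are systematic, not random.

## 4. Statistics

Dunn's test ranks all N observations jointly (midranks on ties) and
compares mean ranks:

    z_ij = (R̄_i − R̄_j) / √[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))·(1/n_i + 1/n_j)],

two-sided normal p-values, Holm adjustment by default (Bonferroni and
none available). A fully tied pooled sample yields z = 0, p = 1. The
type-I error at α = 0.05 is calibrated to 0.05 ± 0.01 at 10⁴ null
replicates (n = 30 per group); on the 3-vs-3 worked example the normal
approximation (p ≈ 0.0495) is anticonservative against the exact
permutation tail (p = 0.1) — expected at such sample sizes, and made
visible by the enumeration oracle in the tests.

Rayleigh's test doubles axial angles onto the full circle (orientation
data are axial: θ and θ+180° are the same orientation), computes
R̄ = |Σe^{iθ}|/n, z = nR̄², and the standard series approximation for p
(clipped to [0,1]; n ≥ 5 required). Under the null the p-values are
uniform (KS D < 0.02 at 10⁴ replicates).

## 5. What the generator does not emulate

No optical image formation (masks are generated directly — segmentation
error of the upstream deep-learning morphometry is out of scope); no
filopodia or shape irregularity beyond the ellipse family, so
shape-fidelity conclusions transfer only to the moment-ellipse summary,
not to boundary-sensitive metrics; platelets do not move, fragment or
merge, so the tracker's identity handling is exercised only by
constructed tests; no drift, no viscoelastic or rate-dependent response,
no electrode drift or 1/f noise in the current (i.i.d. Gaussian only);
the bottom-effect factor φ is the same function in forward and inverse
direction, so the round trip validates the pipeline's self-consistency,
not the physical accuracy of any particular published correction curve.
Passing tests demonstrate that the measurement chain recovers known
inputs under the stated noise model — not that the model captures every
property of real instruments or real platelets.
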