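# Methods

## Physical model and correction

A depth column (A-scan) is a stack of layers, index `n` increasing with
depth, layer 0 at the tissue-facing surface. The structural OCT intensity is
modelled as

    S_n = T_n · R_n / w1

where `R_n` is the reflectivity of layer `n`, `T_n ∈ (0, 1]` the fraction of
incident light transmitted to it (`T_0 = 1`), and `1/w1` a proportionality
constant that also absorbs detector efficiency — which is why `w1` cannot be
derived from first principles and remains a per-dataset tuning weight. The
angiographic (OCTA) intensity is the temporal variation of this product:

    A_n = (δT_n · R_n + T_n · δR_n) / w1

The second term, proportional to the reflectivity variation `δR_n`, is the
true flow signal; the first is the tail artifact: flow in shallower layers
varies the transmitted light `δT_n` and thereby mimics flow at depth.
Treating flow variations of different layers as uncorrelated, the
transmitted-light variation adds in quadrature,

    δT_n = sqrt( Σ_{i<n} δR_i² ) = w1 · sqrt( Σ_{i<n} (A_i^corr / T_i)² ),

which closes the recursion: subtracting the artifact term layer by layer,
shallow to deep,

    A_n^corr = A_n − w1 · (S_n / T_n) · sqrt( Σ_{i<n} (A_i^corr / T_i)² ).

`tartes_correct` implements the standard simplified form (`T ≡ 1`);
`tartes_correct_full` takes an explicit transmittance profile and reduces to
the simplified form bit-for-bit at `T ≡ 1`.

Key properties (all asserted by tests): the corrected volume is
elementwise ≤ the input and non-negative; layer 0 is returned unchanged;
negative amplitudes are non-physical and are zeroed *immediately*, with the
zeroed value feeding the accumulator of deeper layers — feeding negative
amplitudes into a sum of squares would inflate the correction
non-physically.

### Comparators

* **Mean-Subtraction**: `A^corr = max(A − (w2/N)·Σ_{i=1..N} A_i, 0)` with
  `N` the number of layers. The baseline uses the *uncorrected* profile and
  is identical for every layer of the column, so unlike the recursive
  methods it also lowers layer 0 (a documented asymmetry).
* **Step-down Exponential filtering**:
  `A_n^corr = A_n · exp(−w3 · Σ_{i<n} A_i^corr)` with the accumulator over
  *corrected* shallower layers. The factor is always positive, so output is
  strictly positive wherever input is, and nothing clips.
* **Linearized SDEF** (`sdef_linearized`) replaces the exponential by
  `max(1 − w3·Σ, 0)`. It exists as a limit oracle: on a fixed bounded
  volume its maximum relative gap to the exact filter scales as O(w3²),
  checked empirically at `w3 ∈ {1e-2, 1e-3, 1e-4}` (the gap drops ≈100×
  per 10× weight decrease).

### Transmittance estimation

`estimate_transmittance` inverts the structural model per column:
`T_0 = 1`, `T_n = T_{n−1} − w1·S_{n−1}/T_{n−1}` (since
`R_i = w1·S_i/T_i`). When cumulative reflection approaches 1 the recursion
would divide by vanishing numbers, so `T` is clamped at a floor of `1e-3`
and a `RuntimeWarning` is emitted — at that point `w1` is too large for the
volume's intensity scale and the estimate should not be trusted.

## Conventions and numerical choices

* **Array layout**: `(z, y, x)`, depth first, so the "layers shallower than
  `n`" prefix is a leading-axis slice. Layer `n` sits at physical depth
  `n·pitch_z`; user-facing depths are mm, pitches µm.
* **Accumulators**: each recursion keeps one running per-column accumulator
  in double precision, updated once per layer (O(1) per voxel). Unit and
  acceptance tests pin equivalence with naive per-layer prefix re-summation
  and with per-voxel pure-Python recursions at 1e-10 relative.
* **Gaussian smoothing**: sigma defaults to 1 voxel per axis (anisotropic in
  physical units — a deliberate reading of the usual "one voxel" setting,
  exposed as a parameter), reflected boundaries (edge-repeating), kernel
  truncated at 4σ and normalized so constants are preserved. Reflection
  avoids darkening the shallow layers that seed the recursion.
* **Noise floor**: mean intensity over all voxels in a deep-tissue window
  (default 4–7 mm) where only homogeneous noise remains, subtracted with
  clipping at zero. A layer counts as inside the window iff its whole span
  `[n·pitch, (n+1)·pitch)` fits in it; at 8.1 µm pitch the 4–7 mm window
  resolves to layers 494–863. Preprocessing order is smoothing first, then
  floor subtraction, applied to both S and A.
* **En face / offset lookups** use nearest-layer rounding (discretization
  error ≤ pitch/2 ≈ 4 µm, negligible at 0.2 mm offsets); profile peaks are
  global maxima with first-occurrence tie-breaking, for determinism.
* **Intensity units** are arbitrary and linear; the weights are defined
  relative to whatever scale the inputs carry and are never converted.

## Phantom generator

The generator runs the forward model above on parametric geometry:
homogeneous background reflectivity `R` with straight cylindrical vessels
(voxel-centre rasterization, no anti-aliasing — exact, countable geometry)
carrying constant `δR`. `δT` is computed directly from the injected `δR`
field, which at unit transmittance coincides algebraically with the
self-consistent fixed point through `A^corr`; this yields a closed-form
ground truth `A_n^corr = T_n δR_n / w_true` and the flagship inversion
property: `tartes_correct` at `w1 = w_true` recovers it exactly (≤1e-9
relative, in practice ~1e-16) wherever clipping is inactive. In non-unit
mode `T_n = 1 − Σ_{i<n} R_i`, which requires column sums of R below 1; the
full-form corrector with the generated `T` inverts those phantoms exactly
too.

Default phantom: 2.3/2.2/8.1 µm pitch, 256×64×64 voxels (2.07 mm deep),
one vessel of 0.05 mm radius at 1.5 mm depth along x, `w_true = 0.02`,
unit transmittance. Background `R = 0.15` per layer and `δR = 0.004` were
chosen once so that the uncorrected tail plateau reaches ≈35 % of the
vessel peak — a conspicuous artifact of the same order seen in clinical
depth profiles. With ~12 layers of vessel, the tail-to-peak ratio is
approximately `R·sqrt(12) ≈ 0.5` before dilution by the flow term, so these
two numbers jointly set artifact prominence.

Optional noise multiplies S and A by i.i.d. gamma factors with mean 1 and
standard deviation `noise_sigma` (positive by construction, seeded,
reproducible). This emulates the magnitude variability of speckle, not its
coherent statistics; there is no multiple-scattering tail, no motion
artifact, and no detector saturation. Passing tests on phantoms therefore
demonstrate correctness of the *transmittance-variation* inversion, not
robustness to every clinical confound.

## Evaluation metrics

* `residual_at_offset`: profile value at (peak depth + offset, nearest
  layer) divided by the peak value — scale-invariant; the standard readout
  is 0.2 mm below the peak.
* `peak_shift`: corrected minus original peak depth (negative = shallower).
  On the default phantom TAR-TES shifts the peak −0.065 mm: the uncorrected
  peak sits at the vessel's *trailing* edge (the artifact accumulates
  through the vessel) while the corrected peak sits at the true flow
  profile.
* `tail_energy_ratio`: summed intensity in the shadow region (directly
  below vessel-mask voxels, default extent 0.3 mm) over summed in-vessel
  intensity; NaN when the vessel energy vanished entirely.
* `sweep_weights` formalizes manual tuning: run a corrector over a weight
  grid and suggest the smallest weight whose tail ratio falls below a
  threshold (default 0.1 — our choice of scalar stand-in for "tails
  visually gone", echoed in the result). On the default phantom the
  suggestion equals the generating weight.

## Problem sizes and limitations

The test suite and the acceptance script use the default 256×64×64 phantom
(simulation + correction well under a second), 100 seeded 16×8×8 volumes
for oracle equivalence, and small single-column fixtures; the full suite
runs in a few seconds on one core. Known limitations: weights are
dataset-specific and must be re-tuned per acquisition; aggressive weights
cause signal loss and flattened vessel cross-sections; the model addresses
only the transmittance-variation artifact source, not multiple-scattering
path elongation; and speckle-variance computation from repeated B-scans,
raw spectral reconstruction and motion correction are upstream of this
package's scope.
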