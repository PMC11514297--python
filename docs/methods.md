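# Methods

## Signal model and simulator

A 2D hypercomplex FID is a sum of `N` damped complex exponentials sampled
at integer dwell times `t1 = 0..k-1` (indirect) and `t2 = 0..l-1` (direct):

```
X_{P/N}(t1,t2) = Σ_n A_n exp(±i(2π ω1_n t1 + φ1_n)) exp(−t1/τ1_n)
                     · exp( i(2π ω2_n t2 + φ2_n)) exp(−t2/τ2_n) + noise
```

with `+` for the P (echo) and `−` for the N (anti-echo) acquisition.
Defaults emulate a ¹H-¹⁵N correlation plane: `k=128`, `l=256`, `N=512`,
frequencies uniform on the full band `[−0.5, 0.5]` cycles/dwell, phases
uniform on `[−3°, 3°]`, amplitudes on `[−0.2, 1]`, decay times (dwell
units) `[256, 1280]` indirect and `[12.8, 128]` direct, SNR 500.

Decisions worth noting:

* **Indirect envelope sign.** The envelope is implemented as a decay
  `exp(−t1/τ1)`, like the direct dimension; a growing envelope contradicts
  the relaxation interpretation of `τ`. A flag
  (`literal_indirect_growth`) exposes the growing variant.
* **SNR definition.** Per-component Gaussian noise std is
  `1/SNR` — pegged to the maximum attainable single-exponential amplitude
  (1 under the default ranges). P and N receive independent noise draws:
  they are separate acquisitions.
* **Imbalance.** `apply_imbalance(d)` scales `X_P` by `1−d` (the separate
  echo experiment being weaker); imbalance is applied before noise.
* **Seeds.** A master seed maps to per-FID seeds through a counter-based
  `SeedSequence` spawn, so datasets are reproducible and order-independent.

What the simulator does **not** emulate: pulse-sequence transfer functions
(TROSY vs HSQC), solvent signals, t1-noise, baseline distortions and
temperature drifts. Tests passing on this data demonstrate the algorithms'
correctness and their behavior under Gaussian noise and P/N imbalance, not
robustness to every artifact of real spectrometers.

## Processing chain and the Virtual Echo

P/N pairs are converted to amplitude-modulated components
(`cos = (X_P+X_N)/2`, `sin = (X_P−X_N)/(2i)`) and processed dimension by
dimension: apodization (cosine-squared over the acquired points),
zero-filling (×2 per dimension, giving the `2k × 2l` grid every other
module assumes), FFT, and zero/first-order phase correction (defaults 0;
the small simulated phases are left in the data as realistic
imperfections). All arrays are kept in unshifted FFT layout: index 0 is
t=0 (or ω=0), index T is Nyquist, indices above T are negative.

The Virtual Echo of a real spectrum is `VE = iFT2[S]`, conjugate-symmetric
by construction. Quadrants are assigned by the time signs:
P `(+,+)`, P̃ `(−,−)`, N `(−,+)`, Ñ `(+,−)`. The projectors `Z_E` (zero
the P side) and `Z_N` (zero the N side) give every boundary line (t=0 and
Nyquist in either dimension) weight ½ in each projector — the unique
choice for which `Z_E + Z_N = Id` holds exactly, yielding the testable
identity `S_echo + S_anti_echo = S` to machine precision. Both projectors
preserve conjugate symmetry, so twisted spectra are exactly real.

## CS-IST completion

Echo-only (or NUS) data fixes part of the VE; the iteration

```
x ← SoftThreshold_λ( FT[ known + (1 − w) · iFT[x] ] )
```

keeps the measured samples (weights `w`) and shrinks the real spectrum
with a threshold decaying geometrically from `0.9·max|x0|` to a noise
floor estimate (5 × the median absolute spectral value) over 200
iterations, followed by an exact data-consistency projection. Thresholds
are relative to the input scale, so reconstruction commutes with global
scaling. For NUS problems the Nyquist row is treated as known (it is fixed
by the processing convention, not by sampling), which makes a complete
schedule an exact round trip.

Numerical behavior: on well-resolved spectra (e.g. three peaks on a
128×256 grid) echo-only completion reaches RMSD ≲ 3·10⁻³ of the maximum.
On very small grids (≤ 32×64) with strongly truncated signals the IST
fixed point carries a bias of order 1–2% — the spectrum is no longer
sparse relative to the grid — which is why the recovery tests run at the
128×256 spectrum size and the network route is preferable at desk scale.

Poisson-gap schedules draw gap lengths from a Poisson law with a
sinusoidally modulated mean (`rate · sin(π/2 · position)`), front-loading
early increments; the rate is bisected (re-drawing with a fixed seed)
until the target point count is hit exactly, and index 0 is always
sampled.

## The dilated-convolution network and cascade

One network stage is a stack of valid (unpadded) dilated convolutions:
layer 1 a 2×4 kernel without dilation, layer `m` a 2×2 kernel with
dilation `(2^(m−1), 2^m)`, 50 filters and ReLU per layer, closed by a
linear 1×1 projection to one channel (linear so that negative intensities
remain representable). With five layers the receptive field is (31, 63):
a 63×127 patch maps to 32×64. Full spectra are processed in
non-overlapping output tiles with zero-padded margins (receptive field
split ⌊rf/2⌋ before / rest after per dimension); `stitch(tile(x)) = x`
exactly.

The five-stage cascade alternates network application and the correction
`S_cor(i) = S_echo + C(i)·FT[Z_E[iFT[S_pred(i)]]]` with
`C(i) = 1 − 0.05·2^(1−i)`; no correction after the last stage. Stages are
trained sequentially on the frozen upstream outputs. Inputs and targets
are normalized by the Euclidean norm of the stage input spectrum (one
norm per spectrum, not per patch). Training uses Adam (lr 1e−4, batch
64, MSE, up to 1000 epochs) with a 90/10 train/validation split, early
stopping (patience 20) and best-weight restoration. Anti-echo data is
served by reflecting the indirect frequency axis — which maps the
anti-echo twist onto the echo twist exactly — and reusing echo-trained
weights; separate training remains possible.

**Desk-scale configuration.** The package's tests and demo train a reduced
variant: 4 layers / 12 filters (receptive field 15×31), one stage, 16×32
spectra, 200 pairs, 60 epochs at lr 3e−3, batch 32. Under these
conditions a single stage reduces held-out input-vs-reference MSE to
~0.13× the untrained baseline. The full-size architecture and multi-stage
training are supported through the same API (`WNNSpec()`, `n_stages=5`)
but are not exercised by the test suite.

## Uncertainty estimation and pSQ

A second network with the same backbone predicts, from the corrupted
input spectrum alone, the per-point standard deviation `σ` of a fixed
reconstruction method, trained by minimizing the mean Gaussian NLL
`(y−μ)²/(2σ²) + log σ` with the method's reconstruction `μ` fixed. One
predictor is trained per method (network-echo, CS-echo, CS-NUS).
Positivity is enforced by a rectifier plus floor `ε = 1e−6`.

Two numerical safeguards matter in practice:

* the σ head is initialized as a nearly uniform positive map (projection
  weights damped ×0.01, bias 0.5), because a head output at the floor
  makes the likelihood term explode;
* gradients are clipped to a global norm of 10, and the rectifier passes
  gradients on its dead side when they would push the output back up —
  without both, a single near-floor point poisons Adam's moment estimates
  and the training collapses irrecoverably.

Calibration on held-out synthetic data: 95% CI empirical coverage ≈ 0.97
for the CS-echo predictor trained at desk scale; on benchmarks with known
noise (constant σ₀, or σ₀ ∝ |input|) the learned σ recovers the scale
within 20% and rank-correlates with the true heteroscedastic profile
(Spearman ρ ≈ 0.7).

**pSQ** normalizes a σ map by the maximum absolute intensity of the
reconstruction and summarizes the normalized values over the support
(points above 1% of that maximum) as box-plot statistics. The headline
statistic is the median (robust); the mean is reported alongside. pSQ is
invariant under joint rescaling of (reconstruction, σ) and monotone in σ.
Because it never touches a reference spectrum, it scores Echo and
Anti-Echo reconstructions of P/N-imbalanced data as equal (within
sampling noise), while reference-based RMSD is biased by the residual
twist in the imbalanced reference.

## Reference-based metrics

RMSD and R²s compare a reconstruction to a reference after each is
normalized by its own maximum absolute intensity, restricted to the
support: points above 1% (absolute value, so dispersive artifacts count)
of the maximum in *either* spectrum — sensitive to both false-positive
and false-negative artifacts. R²s is the squared Pearson correlation over
the support. Both accept `normalize=False` for comparisons on a common
intensity scale.

## File formats

Real spectra: NMRPipe-style 2D binary (512 float32 header words with the
byte-order sentinel, dimension count, sizes and domain flags populated;
row-major float32 data — single-precision round trip) and a lossless HDF5
container. FIDs, VE arrays, σ maps, datasets and network checkpoints use
the HDF5 container, with generating configurations echoed as YAML for
provenance. NUS schedules are plain text, one zero-based integer per
line. Run configurations are YAML with strict key validation and a
mandatory seed.

## Known limitations

* Training is CPU-numpy; full-scale five-stage training on 1024 pairs of
  256×512 spectra is supported by the API but slow — the reduced
  configuration above is the intended desk-scale operating point.
* The IST solver inherits the small-grid bias described above.
* First-order phasing of experimental data, linear prediction, solvent
  suppression, and vendor raw-data formats are out of scope; so are ≥3D
  virtual-echo variants and alternative CS solvers.
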