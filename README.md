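# echorecon

Tools for 2D NMR processing beyond traditional quadrature detection:
reconstruction of pure-absorption spectra from a **single** phase-modulated
dataset (P-type/Echo *or* N-type/Anti-Echo), per-point intensity
**uncertainty estimation** for any reconstruction method, and a
**reference-free spectrum quality score** (pSQ).

## The problem

Gradient coherence-selection experiments deliver two phase-modulated
datasets per 2D plane,

```
X_P(t1, t2) = exp(+i Ω1 t1) exp(i Ω2 t2)      (P-type, Echo)
X_N(t1, t2) = exp(-i Ω1 t1) exp(i Ω2 t2)      (N-type, Anti-Echo)
```

and a pure-absorption spectrum classically requires both: either one alone
Fourier-transforms into a *phase-twisted* lineshape. In the **Virtual
Echo** picture — the complex time-domain array `VE = iFT[S]` of a real
spectrum `S` — the four time-sign quadrants carry `P`, `N` and their
time-reversed conjugates, so discarding one quadrature is equivalent to
zeroing half of the VE. Rectifying the twist therefore becomes a *data
completion* problem, solvable by:

* **CS-IST** — compressed-sensing iterative soft thresholding, which fills
  the missing quadrants with the sparsest consistent spectrum, and
* a **cascade of dilated convolutional networks** that recognizes the 2D
  twist pattern in the frequency domain. Five stages are chained with the
  correction `S_cor(i) = S_echo + C(i)·FT[Z_E[iFT[S_pred(i)]]]`,
  `C(i) = 1 − 0.05·2^(1−i)`, which restores the measured Echo part exactly
  between stages.

A second network, trained with the Gaussian negative log-likelihood
`NLL(y|μ,σ) = (y−μ)²/(2σ²) + log σ` with the method's reconstruction `μ`
held fixed, predicts the per-point standard deviation `σ` of any fixed
reconstruction method from the corrupted input alone. Normalizing `σ` by
the reconstruction's peak intensity and summarizing it over the spectral
support (points above 1% of the maximum) yields **pSQ**, a spectrum quality
score that needs no reference spectrum — and is therefore immune to biased
references, e.g. when the P and N amplitudes are imbalanced.

Everything runs on synthetic 2D ¹H-¹⁵N-like data generated by the built-in
simulator (sums of damped complex exponentials with configurable frequency,
phase, decay and amplitude ranges, Gaussian noise, optional P/N imbalance),
processed with a standard hypercomplex chain (apodization, zero-filling,
FFT, phasing). The networks and their training (Adam, MSE/NLL, early
stopping) are implemented on numpy.

## Worked example

```python
import numpy as np
import echorecon as er

cfg = er.scaled_config()                       # 16 x 32 spectra, SNR 500
train = er.generate_pairs(cfg, 200, "echo", master_seed=11)
test  = er.generate_pairs(cfg, 30, "echo", master_seed=999)

model = er.CascadeReconstructor(n_stages=1, spec=er.scaled_spec(),
                                output_extent=(16, 32), learning_rate=3e-3,
                                batch_size=32, max_epochs=60, patience=60,
                                random_state=5)
model.fit(train.inputs, train.references)
pred = model.predict(test.inputs)

mse_model = np.mean((pred - test.references) ** 2)
mse_twist = np.mean((test.inputs - test.references) ** 2)
print(f"MSE ratio vs raw echo input: {mse_model / mse_twist:.3f}")

rec_cs = er.ISTReconstructor("echo").transform(test.inputs[0])
print(f"CS RMSD: {er.rmsd(rec_cs, test.references[0]):.4f}  "
      f"R2: {er.r2(rec_cs, test.references[0]):.4f}")
```

prints (exact numbers depend on the numpy build)

```
MSE ratio vs raw echo input: 0.126
CS RMSD: 0.0680  R2: 0.8647
```

i.e. a single trained stage removes ~87% of the phase-twist error energy
on held-out spectra, while CS-IST on the same tiny 16×32 grid is limited
by its small-grid bias to ~7% RMSD (it reaches sub-1% RMSD on larger,
well-resolved grids — see `tests/test_acceptance.py`).

The same pipeline is scriptable from the shell:

```sh
echorecon demo --seed 5 --outdir demo_out      # end-to-end scaled pipeline
echorecon simulate --count 64 --seed 3 --out pairs.h5
echorecon train pairs.h5 --out cascade.h5
echorecon nus-schedule --n 128 --fraction 0.5 --out sched.txt
```

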