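# dmdmotion

Short-term anticipation of human body motion — and of multivariate,
quasi-periodic time series in general — using **exact dynamic mode
decomposition (DMD)** with **delay-coordinate embedding**.

## The problem

Given a window of recorded motion (e.g. 17 skeletal markers × 3
coordinates sampled at 50 Hz), predict the next few hundred milliseconds
of movement.  Neural sequence models can do this, but as black boxes.
This package takes the linear, interpretable route: fit a best linear
one-step propagator to the observed snapshots and extrapolate it.  It is
aimed at researchers in biomechanics, robotics and human movement
analysis who need short-horizon pose forecasts with an inspectable model
and no training corpus — the method fits each motion clip on its own.

## The method

For snapshots $x_1,\dots,x_n \in \mathbb{R}^m$, exact DMD computes the
spectral decomposition of the least-squares propagator $A = Y X^{+}$
(where $X = [x_1 \dots x_{n-1}]$, $Y = [x_2 \dots x_n]$) through the
reduced SVD $X = U\Sigma V^{*}$: the eigenpairs $(\lambda_i, v_i)$ of
$S = U^{*} Y V \Sigma^{-1}$ give modes
$\vartheta_i = \tfrac{1}{\lambda_i} Y V \Sigma^{-1} v_i$ and amplitudes
$a = \Lambda^{-1}\Theta^{+}x_2$, so that

$$x_k \approx \Theta\,\Lambda^{k-1}a, \qquad k = 2,\dots,n,\; n+1,\dots$$

A single frame of a scalar or low-dimensional observable carries too
little state for this to work (one sample of an oscillation has no
phase).  The fix is Takens-style **delay embedding**: stack $d{+}1$
consecutive frames into augmented state vectors, giving a Hankel-block
matrix with $(d{+}1)m$ rows and $n{-}d$ columns, and run exact DMD on
that ("DMDd").  Delay embedding turns unforecastable signals into
near-exactly reconstructible ones; the number of delays trades bias
(too few frequencies) against variance (too few columns), so
anticipation error typically has an interior minimum in $d$.

The package provides:

- `dmd_core` — exact DMD: fitting, reconstruction, forecasting, and a
  brute-force spectral oracle ($Y X^{+}$ eigenvalues) for validation;
- `delay_embedding` — the Hankel stacking, DMDd fitting, forecast
  readout and reconstruction;
- `metrics` — batch MSE over pose sequences and a pooled-histogram KL
  divergence;
- `synthetic` — generators with known ground truth: linear systems,
  (quasi-periodic) sinusoid mixtures, and a 51-channel walking-like
  skeleton;
- `experiments` — the evaluation protocol: motion CSV I/O,
  sub-sequencing, marker subsets (M1/M5/M17), simulated accelerometers
  (second time derivatives), anticipation runs and delay sweeps, with a
  deterministic error-table CSV output;
- a `dmdmotion` CLI (`synth`, `fit`, `predict`, `eval`, `sweep`).

## Worked example

```python
import dmdmotion as dm

corpus = dm.demo_corpus(n=450, noise_sd=1.0, seed=0)   # 3 labelled classes
cfg = dm.ExperimentConfig(subseq_len=150, input_len=100, delays=20)
table = dm.run_anticipation(corpus, cfg)
print(table.frame.to_string(index=False))
```

```
class  delay  horizon_frames  horizon_s metric       value  K
march     20               5        0.1    mse    1.749813  3
march     20              10        0.2    mse    2.691925  3
march     20              20        0.4    mse    7.691290  3
 sway     20               5        0.1    mse  582.804054  3
 sway     20              10        0.2    mse 1090.932421  3
 sway     20              20        0.4    mse 3673.951646  3
 walk     20               5        0.1    mse    1.523290  3
 walk     20              10        0.2    mse    1.966199  3
 walk     20              20        0.4    mse    3.802296  3
```

Each row is the mean squared error (mm², averaged over the K = 3
sub-sequences of a class) of forecasting 0.1/0.2/0.4 s ahead from 2 s of
input with 20 delays.  The two skeleton classes (`walk`, `march`, noise
floor 1 mm → MSE ≈ 1 mm²) are anticipated almost down to the noise; the
harder incommensurate-frequency class (`sway`) shows the characteristic
error growth with horizon.  The same run from the shell:

```sh
dmdmotion synth --out walk.csv --frames 450 --noise-sd 1 --seed 1
dmdmotion eval --data walk=walk.csv --subseq-len 150 --input-frames 100 \
               --delays 20 --out errors.csv
dmdmotion sweep --data walk=walk.csv --subseq-len 150 --input-frames 100 \
                --delays 10,20,40,60,80 --mode anticipation --out sweep.csv
```

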