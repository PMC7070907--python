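# Methods

## Model

The package models a multivariate motion time series
$x_1,\dots,x_n\in\mathbb{R}^m$ as the output of a linear dynamical
system: a propagator $A$ with $x_{k+1}\approx Ax_k$, fitted by least
squares and represented spectrally by DMD eigenvalues $\lambda_j$
(per-step complex multipliers: modulus = growth/decay, phase =
oscillation frequency), modes $\vartheta_j$ (spatial patterns over the
observables) and amplitudes $a_j$.  The model state at frame $k$ is
$\Theta\Lambda^{k-1}a$; frames beyond $n$ are forecasts.

The assumptions are: the dynamics over the fitting window are
approximately linear and diagonalizable; the observables are real; and
for raw (un-embedded) data, the snapshot count does not exceed what the
observable dimension can support.  When $m > n$ and $X$ has full column
rank and no eigenvalue falls below the modulus tolerance, fitting is
interpolation and the reconstruction of frames $2..n$ is exact — a
property the test suite checks to $10^{-8}$ relative error.  Human-scale
motion data is in the opposite regime ($m < n$), which is exactly where
delay embedding is needed.

### Exact DMD details

* Reduced SVD $X=U\Sigma V^*$ with rank cut `svd_tol` = 1e-12
  **relative** to the largest singular value.  The algorithm assumes an
  exact rank, which floating point never provides; the relative cut
  discards only numerically-zero directions.
* Eigenvalues of $S=U^*YV\Sigma^{-1}$ with modulus below `eig_tol` =
  1e-12 (absolute) are dropped; they correspond to directions the
  one-step map annihilates and have no invertible dynamics.  If *all*
  eigenvalues are dropped (e.g. pure shift data) the fit raises a
  degenerate-spectrum error rather than returning an empty model.
* Amplitudes solve $a=\Lambda^{-1}\Theta^{+}x_2$ with the pseudoinverse
  computed by SVD at the same relative tolerance.  Fitting to the
  *second* snapshot means frame 1 is never reconstructed; all
  reconstruction APIs therefore start at $k=2$.
* Reconstruction and forecast return real parts.  For real input the
  spectrum is conjugation-closed and the imaginary parts cancel to
  rounding; the largest relative imaginary residue seen is recorded in
  `model.diagnostics["max_imag_residue"]` as a health check.
* Forecasts of unstable fits may overflow.  The policy is to propagate
  `inf`/`nan` instead of raising: delay sweeps must be able to visit an
  unstable delay count and report it, and the metrics score non-finite
  predictions as `+inf` error.

### Delay embedding

`delay_embed` stacks $d{+}1$ shifted copies of the series into a matrix
with $(d{+}1)m$ rows and $n{-}d$ columns; block row $b$ of column $j$ is
base frame $x_{j+b-1}$.  The admissible range is $0\le d\le n-3$: the
upper end leaves a three-column window, the smallest whose snapshot pair
still has two columns, and $d=0$ is the identity embedding (plain DMD),
so sweeps cover both regimes through one code path.  Published
protocol settings that pair a 1 s (50-frame) input with 80 delays are
inadmissible under this window arithmetic; the implementation refuses
such configurations with an error naming the admissible interval rather
than silently reinterpreting either parameter.

Forecasting advances the augmented state by eigenvalue powers
($\Theta\Lambda^k a$ in the augmented space) and never re-stacks
predicted frames into a new embedding — the linear-model formalism
implies the former and it avoids error feedback.  Two readout policies
map augmented forecast columns to base frames: `bottom_block` (default)
takes the newest block, the natural anticipation target; the
`average_blocks` option averages every block estimate of the same base
frame, useful as a robustness study on noisy data.  For data that truly
follow a linear recurrence, all overlapping block estimates coincide (a
tested invariant), so the policy only matters off-model.
Reconstruction reads frame $j\ge d+2$ from the bottom block of
augmented column $j-d$; early frames $2..d{+}1$, which have no column
with themselves at the bottom, are read from the deepest available
block of augmented column 2.

### How many delays

A scalar signal with $q$ rationally independent frequencies occupies
$2q$ complex-exponential dimensions, so the embedding window needs
$d+1\ge 2q$ rows before the augmented matrix can have full dynamic
rank; below that the fit is structurally under-resolved and its error
fluctuates erratically with $d$, while above it the reconstruction
error collapses by many orders of magnitude.  On noisy data,
anticipation error instead attains an interior minimum in $d$: small
windows miss frequencies (bias), large ones leave too few columns and
fit noise (variance).  The package deliberately offers no automatic
selection of $d$ — sweeps with `run_delay_sweep` are the supported way
to choose it empirically.

## Metrics

`pose_mse` implements the batch mean squared error: inner mean over the
$m\cdot p$ entries of each sequence, outer mean over the $K$ sequences
of a class; units mm² for positional data, (mm/s²)² for accelerations.

`pose_kl` is a Kullback–Leibler divergence between pose distributions.
The construction in the literature this mirrors is under-specified, so
the package documents its own reading prominently: all ground-truth
coordinate values are pooled into one histogram $Q$ and all predicted
values into $R$, over their joint min/max range with `bins` = 100;
both histograms are smoothed by `eps` = 1e-10 per bin and renormalised;
the reported value is $\mathrm{KL}(Q\Vert R)=\sum Q\log(Q/R)$.
Alternative readings (per-joint histograms, the reverse direction,
different binning) would give different numbers; comparisons across
publications should not assume this particular construction.

## Synthetic data

The generators define the test conditions of the whole package:

* `linear_system_series` — exact linear dynamics, the oracle class.
* `sinusoid_series` / `quasi_periodic_scalar` — sums of sinusoids with
  per-frame damping factors and i.i.d. Gaussian noise; the
  quasi-periodic default uses five incommensurate frequencies
  (1, √2, √3, √5, √7 Hz) at 50 mm-scale amplitudes.
* `synthetic_skeleton` — 17 joints × 3 coordinates at 50 Hz.  Limb
  channels oscillate at the gait frequency (default 1 Hz) and its first
  two harmonics around fixed anatomical offsets, with amplitudes from
  15 mm (head) to 280 mm (feet); right-side joints are shifted by half
  a gait cycle, and the even harmonic is kept weak so paired left/right
  channels correlate below −0.9.  The root travels forward as a
  very-low-frequency sinusoid (0.05 Hz, 2 m amplitude ≈ 0.6 m/s walking
  speed): over any clip this is linear drift to high accuracy, but
  unlike a true ramp it keeps every channel an exact sum of at most 7
  complex exponentials, so the noise-free skeleton is exactly low-rank
  after delay embedding — the property that grounds the near-machine-
  precision reconstruction tests.
* `demo_corpus` — the three-class labelled corpus used by the protocol
  tests and the acceptance script: two skeleton classes at different
  cadences plus a three-channel quasi-periodic class, 450 frames each
  (three 150-frame sub-sequences) with 1 mm measurement noise.
* Noise defaults: Gaussian, i.i.d. per channel and frame, 1 mm standard
  deviation in protocol runs — mm-scale noise on mm-scale marker data,
  giving forecast MSE magnitudes commensurate with marker-based pose
  anticipation studies (10⁰–10³ mm²).  All generators require an
  explicit seed; there is no hidden global randomness.

What the synthetic data does **not** emulate: bone-length constraints
and joint limits, intent changes or transitions between actions,
non-stationary amplitude envelopes, sensor dropout, or the broadband
spectral content of real motion capture.  Passing tests therefore show
that the implementation is faithful to the method and that the method
behaves as theory predicts on signals satisfying its assumptions — not
that real-data error magnitudes will match.

## Evaluation protocol

Each labelled series is split into non-overlapping sub-sequences
(default 150 frames; a stride parameter allows overlapping studies;
trailing remainders are dropped, not padded).  The first `input_len`
frames (default 100 = 2 s) are the model input; forecasts are scored at
horizons of 5, 10 and 20 frames (0.1/0.2/0.4 s at 50 Hz) against the
held-out continuation, averaged over each class's K sub-sequences.
Marker subsets follow the M1/M5/M17 convention (one target joint; root
plus the four end effectors, 15 channels; all 17 markers, 51 channels).
Simulated accelerometers are central second differences
$(x_{k+1}-2x_k+x_{k-1})\,\mathrm{fps}^2$, two frames shorter than the
input, fed through the identical pipeline with no special-casing.
Delay sweeps score either reconstruction (frames $2..$`input_len`,
reported as horizon 0) or anticipation at the largest configured
horizon, one table row per (class, delay).  Error tables are sorted
class-alphabetical, delay-ascending, horizon-ascending and written with
17-significant-digit floats, so identical configurations produce
byte-identical CSVs.

## Numerical and design notes

* Time indexing is 1-based in the mathematics ($x_1..x_n$) and 0-based
  in arrays; every API docstring states which frame its indices refer
  to.  Columns are time internally; rows are time in `MotionSequence`
  and in motion CSVs.
* Eigenvalue multisets are compared (in tests) by greedy
  nearest-neighbour matching rather than sorting, which is robust to
  ties in modulus.
* The `predict` CLI command refits from the input CSV rather than
  loading a serialized model: a forecast needs the embedding
  bookkeeping as well as the decomposition, and the fit is a single
  SVD.  `DMDModel` JSON serialization exists for archiving the
  decomposition itself.
* Problem sizes in the test suite and acceptance script (450-frame
  corpora, 100-frame inputs, delay grids up to 90) were chosen as the
  smallest sizes at which every qualitative regime — under-resolved,
  exact, and overfitted — is visible.

## Known limitations

* Plain DMD (d = 0) on standing-wave-like data can place eigenvalues
  slightly outside the unit circle; long forecasts then overflow by
  design (see the `inf` policy above).
* Defective (non-diagonalizable) dynamics — e.g. a true linear ramp —
  are outside the model class; the fit degrades gracefully but is not
  exact.
* A linear system with $r$ active modes cannot be identified from an
  embedded window with fewer than $r$ snapshot columns; at extreme
  delay counts ($n-d$ close to 3) exactness claims hold only for
  dynamics of correspondingly low dimension.
* No automatic delay selection, no mode visualisation, and no other DMD
  flavours (compressed, randomized, optimized).
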