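# Methods

`mipso` implements a complete motor-imagery BCI decoding chain — spectral
feature extraction, Bayesian linear classification, and wrapper
channel/feature selection — together with the synthetic data needed to test
every stage against planted ground truth.

## Signal model and feature extraction

Input data are two-class trials of multichannel cortical recordings, stored
as a `trials x channels x samples` tensor with labels in {-1, +1}.  Trials
recorded at a high rate are first low-passed (8th-order Butterworth at
0.8x the target Nyquist, applied forward-backward so trial-locked latencies
are untouched) and decimated by an integer factor, e.g. 1000 Hz -> 100 Hz.

Features are time-averaged power of the modified Stockwell transform (MST).
The Stockwell transform analyses x(t) with a Gaussian window whose standard
deviation is sigma(f) = 1/f; the modified transform generalises this to

    sigma'(f) = p / f^q,

so p < 1 trades frequency resolution for sharper time localisation at every
frequency.  Defaults are p = 0.85, q = 1, chosen as the best-performing
operating point for this task family.  The analysis grid is integer
frequencies 1–35 Hz, covering the mu and beta rhythms that motor imagery
modulates; the f = 0 row (the signal mean) is never computed.  Each
(channel, frequency) pair contributes one feature,

    feature(c, f) = mean_tau |S_c(tau, f)|^2,

the mean (not the sum) over the trial's time axis, so the feature scale is
invariant to trial length.  No edge windowing is applied.  With 64 channels
this yields 2240 features per trial.

Numerically, each frequency row is computed as a circular convolution of
the demodulated signal with the *sampled, periodised* Gaussian window,
evaluated with one FFT pair per frequency (O(N log N) per row).  Because
the window's spectrum is obtained by FFT of its time samples rather than by
sampling the continuous-frequency Gaussian, the fast path agrees with the
literal double-sum discretisation of the transform to machine precision;
the test suite checks this against an independent double-loop oracle, along
with the time-marginal property (summing S(tau, f) over tau recovers the
Fourier spectrum) and the exact reduction to the standard transform at
p = q = 1.

## Classifier

The classifier is Bayesian linear regression onto the +-1 labels — the
evidence-framework form of regularised linear discriminant analysis.  A
zero-mean Gaussian prior with precision `alpha` on the weights and Gaussian
noise with precision `beta` are both estimated by fixed-point maximisation
of the marginal likelihood:

    gamma  = sum_i  beta s_i^2 / (beta s_i^2 + alpha)
    alpha <- gamma / ||m||^2
    beta  <- (n - 1 - gamma) / ||y - X m - b||^2

where s_i are the singular values of the centred design and m the posterior
mean.  The bias is excluded from the prior; with features standardised and
centred (the default) it decouples exactly and equals the mean target, and
the `n - 1` in the beta update counts that unpenalised degree of freedom.
Iterations run on the thin SVD of the design, so each update is O(min(n, D))
after one decomposition — important because the wrapper fitness below calls
`fit` tens of thousands of times.  Convergence is declared at a relative
hyperparameter change below 1e-6, with a cap of 200 iterations and
hyperparameters clipped to [1e-12, 1e12] to keep separable problems finite.

Two documented choices the data do not dictate: targets are the raw -1/+1
labels (a `balanced` coding rescaling targets by inverse class size is
available), and features are z-scored from the training split before
fitting — without this, wrapper selection over PSD columns spanning orders
of magnitude is biased toward high-power frequencies.  Hard decisions
threshold the score at zero, with scores exactly 0 assigned to class +1.

Duplicating every training row leaves predicted labels unchanged but is not
bit-exact for the scores: the evidence update for `beta` sees 2n samples
with the same residual structure, shifting the fixed point by O(gamma/n).

## Evaluation metrics

Two-class confusion counts with +1 as the positive class; accuracy and
kappa = (acc - 0.5)/(1 - 0.5) as proportions; sensitivity, specificity,
precision and F-score (harmonic mean of precision and recall) in percent,
displayed at two decimals.  Rates with zero denominators raise an explicit
error rather than returning 0.  Note the harmonic mean lies between
min(precision, recall) and max(precision, recall), with equality only when
the two agree.

## Binary PSO and multilevel selection

Selection masks are bit vectors (one bit per channel or per feature
column).  Velocities follow

    v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x),

with fresh U(0,1) draws per particle-dimension, a linearly decreasing
inertia w(t) = w_max - (w_max - w_min) t/T, and boundary absorption
clamping components to +-v_max.  Positions are resampled bitwise with
P(bit = 1) = sigmoid(v).  Updates are synchronous: all velocities against
the previous iteration's gbest, then all positions, then fitnesses, then
the pbest/gbest records — so the gbest trace is non-decreasing by
construction.  Defaults: N = 100 particles, T = 100 iterations,
c1 = c2 = 1.5, w 0.8 -> 0.4, v_max = 20.  Position bounds are vacuous in
binary coding; absorption applies to velocity only.  One master seed
determines the entire trajectory.

The wrapper fitness of a mask is 1/(SSE + eps) where SSE is the squared
error of the discriminant's thresholded predictions on evaluation trials
(k misclassified trials give SSE = 4k) and eps = 1e-12 keeps a perfect mask
finite.  An all-zero mask scores -inf, as does a degenerate training split.
Ties at the perfect cap are broken toward fewer selected bits (a perfect
mask cannot be improved, so the smaller one wins), then toward the earlier
particle; below the cap ties keep the incumbent, because on a small
validation set imperfect ties are mostly noise and aggressive shrinkage on
them discards useful coordinates.  By default the evaluation trials are a
seeded stratified 25% split carved from the training set, so no test labels
leak into selection; `fitness_on_eval=True` scores fitness on the explicit
evaluation set instead, reproducing protocols that optimise directly
against the test data (useful for comparison, methodologically unsound).
Raw-score squared error is available via `use_scores=True`.

Multilevel selection repeats the PSO, level ell + 1 searching only the
coordinates level ell's gbest retained; the search space is re-indexed so
the particle-to-dimension ratio improves at depth.  Each level starts a
fresh, independently seeded swarm (per-level seeds derive from the master
seed and the level index).  The loop stops at `max_level` (default 10) or
as soon as two consecutive levels select the same *count* of coordinates —
count equality rather than set equality, since a stabilised count is the
observable signal that the selected set has stopped shrinking; set equality
terminates trivially anyway.
Channel granularity maps one bit to a channel's whole 35-column block;
channel-then-feature runs the channel phase to termination and then feature
levels restricted to the survivors' columns.

## Synthetic data

Every channel carries unit-variance 1/f^gamma noise (gamma = 1 by default,
spectrally shaped white noise, no DC).  Informative channels add
band-limited oscillations (order-4 zero-phase Butterworth band-passed white
noise, so phase varies across trials) in the mu (8–12 Hz) and beta
(18–26 Hz) bands.  Class structure enters through band power: in each band
the oscillation's power is multiplied by (1 + e) for one class and (1 - e)
for the other, with the favoured class alternating across bands;
e = 0.8 by default.  The oscillation's standard deviation is
`amplitude` = 0.2 relative to the noise floor, with a lognormal per-trial
amplitude factor (sigma = 0.3) shared across a band's channels.  These two
values were set once, for realism: single-trial, single-channel motor
imagery discriminability in real recordings is modest (roughly 60–75%
accuracy), and event-related power changes fluctuate strongly from trial to
trial.  A consequence worth stating plainly: all informative channels carry
the *same* class contrast, so they are statistically redundant — a small
subset of them already achieves near-maximal accuracy, which is exactly the
situation channel selection exists for, and it means a wrapper selector is
expected to return a minimal sufficient subset rather than the full
informative set.

What the generator does not emulate: real cortical waveform morphology,
artifacts, inter-electrode spatial correlation, or session
non-stationarity.  Passing tests therefore demonstrate that the pipeline
recovers planted band-power structure under realistic noise, not that it
handles the full messiness of recorded data.

## Desk-scale study sizes

The planted-recovery study in the acceptance tests uses 32 channels
(8 informative), 200 trials of 1 s at 100 Hz, a stratified 25% held-out
test split, 10 seeds, and a 24-particle, 30-iteration swarm per level with
`max_level = 10`.  These sizes keep the full study to a few minutes while
preserving the qualitative behaviour of interest: multilevel shrinkage
(feature counts fall from ~550 to under 20 before the count stabilises),
progressive enrichment of planted columns across levels, and chance-level
performance on null data.  The analytic and transform/optimizer/classifier
checks run at the sizes stated in their tests.

## Known limitations

- With ~38 validation trials, the wrapper fitness resolves accuracy
  differences of only ~2.6 points; coordinates whose marginal value is
  smaller drift in and out of the selection.  Deep multilevel runs
  therefore over-shrink on small data, and the deepest level is not always
  the best one — the per-level reports exist so users can pick by
  validation fitness.
- The evidence iterations assume a unimodal evidence surface; with heavy
  collinearity the alpha/beta fixed point can be slow, hence the iteration
  cap.
- No multiclass support, no kernelised discriminant, no continuous-space
  PSO variants.
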