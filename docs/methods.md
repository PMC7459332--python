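# Methods

`mlipop` reimplements, as a tested library, the analysis chain used to study
cerebellar molecular-layer-interneuron (MLI) ensemble Ca²⁺ activity during
head-fixed go–no go olfactory learning, together with a reduced
conductance-based stellate-cell/Purkinje-cell (SC–PC) microcircuit model of
the chemogenetic behavioral result. Because the raw two-photon dataset is an
external deposit, every stage is driven by a synthetic-session generator that
reproduces the statistical structure the analyses assume. This note records
the model choices, parameter conventions and known limits.

## Task model and behavioral scoring

A trial begins with the animal's lick on the water spout; the odorant arrives
after a uniform 1–1.5 s delay and stays on for two consecutive 2-s lick
segments (4 s). On rewarded-odorant (S+) trials a lick in *each* segment is a
Hit and triggers the water reward; otherwise the trial is a Miss. On
unrewarded (S−) trials licking in both segments is a False Alarm (FA),
anything else a Correct Rejection (CR). The inter-trial interval is uniform
22.3–22.8 s, extended by a 10-s timeout after an FA. Segments are half-open
`[on, on+2)` and `[on+2, on+4)`, so a boundary lick belongs to the later
segment; the task description does not fix this convention and ours is
declared in `behavior.score_trial`.

Percent correct is the fraction of correct (Hit/CR) trials in a 20-trial
window sliding by one trial, assigned to the window's last trial; values
before the first full window are undefined. Epochs: ≤65 % naive, ≥80 %
proficient, otherwise intermediate. Lick rates are binned on the requested
grid and optionally convolved with a Gaussian kernel; the "2-s Gaussian" of
the imaging analyses is implemented as SD = 2 s, truncated at ±3 SD and
renormalized — the width convention is ours, since the source does not define
one.

The reward latency is likewise unprinted; the generator delivers the reward
at odor offset, consistent with the trial-period markers of the task figure.
The lick channel is sampled at 100 Hz (declared; the acquisition hardware
rate is unstated).

## Synthetic sessions

`synth.generate_session` draws trial valences (Bernoulli `p_splus`), target
outcomes from a sigmoid learning curve (chance → asymptote, per-trial
probability of a correct response), timing marks, and outcome-specific lick
trains built from jittered near-regular spans: Hits lick through both
segments and burst after the reward at `6 + 3·reward_volume` Hz (>8 Hz at
the default volume), CRs stop licking within 0.4–0.8 s of odor onset, Misses
leave one segment empty, FAs lick both segments without a reward burst.
Scoring a generated train always reproduces the intended outcome; this
round-trip is asserted at generation time.

Ensemble ΔF/F is a factor model. One shared factor carries the task signal:
an early transient (amplitude `amp_sminus`) on both valences during the
first ~0.8 s of odor, plus an S+-specific ramp from trial start to reward
whose amplitude `amp_splus` is scaled by the instantaneous expected
performance mapped onto [0, 1] (chance → 0, asymptote → 1) — so naive
sessions show overlapping S+/S− responses and proficient ones diverge. The
factor is convolved with a unit-area exponential Ca²⁺-indicator kernel
(default decay 0.6 s, a GCaMP6f-scale value). The remaining `n_latents − 1`
factors are smoothed Gaussian noise, orthogonalized in time against the
signal factor and rescaled to its empirical SD; ROI loadings form equal-norm
orthogonal columns, with the signal loading supported on a `frac_responsive`
subset. Equal factor variances with orthogonal loadings make the
participation-ratio dimensionality of the noiseless signal equal `n_latents`
exactly, which is what the dimensionality-control tests exploit. Independent
Gaussian measurement noise (`noise_sd`, ΔF/F units) is added per ROI and
frame, and raw fluorescence is `F = F0·(1 + ΔF/F)` with `F0 = 100` a.u.

Inside the reinforcement window (1.5 s after reward) of rewarded trials the
signal factor is overwritten with a standardized mixture
`ρ·z(lick rate) + √(1−ρ²)·η`, where `z` is the session's 2-s-Gaussian-
smoothed lick rate standardized over the pooled window frames and `η` is
white noise. The pooled Pearson correlation between ensemble-mean ΔF/F and
the lick rate in that window therefore targets `rho_reinforcement`
(default 0.73) by construction; the correlation stage recovers it to within
sampling error (±~0.03 at 80 trials). This component enters after the
indicator convolution because it is built from an already-smooth rate trace.

Kinematics are a tonic nonnegative baseline plus Gaussian bumps locked to
each lick plus low-passed noise; acceleration is the first difference times
the sampling rate.

What the generator does **not** emulate: sniffing, pixel-level imaging
noise, motion artifacts, ROI-segmentation errors, heterogeneous per-ROI
kinetics, slow drift, and any nonstationarity beyond the learning curve.
Passing tests therefore certify the *analysis code* under the stated
statistical structure, not the biology of real sessions.

## ΔF/F and eventization

`compute_dff` uses per-trial baselines: for each trial, `F0` is the mean
fluorescence over the 2 s before the trial-initiating lick, applied to the
frames from that trial start to the next ("before trial start" is read as
per-trial; the baseline length is our choice). The operation is exactly
scale-invariant and errors on non-positive baselines naming the ROI and
trial.

Trial alignment is nearest-frame to trial start, odor onset, reward, or the
detected ΔF/F onset; trials missing the event or exiting the recording are
dropped with a logged count. Period windows: pre-odorant `[−1, 0)` s before
odor onset, odorant = last 1 s of application, reinforcement `[0, 1.5]` s
after reward. ΔF/F onset is the first post-odor frame where the per-frame
first difference of the ensemble-mean trace exceeds 0.03 — the threshold is
applied per frame at 5.3 Hz, matching the printed value's scale; units are
exposed in the call.

Responsiveness follows the 2.5×SD rule with baseline statistics taken from
the 10–2 s pre-odor interval. The criterion's SD is pooled over *single*
(trial, frame) baseline samples, and the deviation is evaluated on the
trial-averaged trace with a strict inequality. Pooling over single trials is
deliberate: measuring the SD on the averaged trace itself makes the
any-frame test scale-free, with a ~23 % false-positive rate on white noise
regardless of noise level, whereas the per-trial pooling keeps the criterion
anchored to trial-to-trial variability (false positives ≈ 0 on noise-only
ROIs, while genuine responses a few baseline-SDs tall are retained).

## Decoding and dimensionality

The decoder is Fisher's linear discriminant with equal class priors and a
pooled within-class covariance regularized by `γI`, `γ = 10⁻⁶·trace/M`, so
it remains defined with more ROIs than trials; priors are equal because
sessions are class-imbalanced. Accuracy is leave-one-out: each trial is
classified by the discriminant fit to all others. The implementation is
checked in the tests against two independent routes — a brute-force
Fisher-rule oracle (explicit pooled covariance, pseudo-inverse whitening,
nearest class mean) on ≤8-trial sets, and an off-the-shelf LDA on
well-conditioned data.

The shuffled-label control band is the bootstrap 95 % interval of the
*distribution* of shuffled-label accuracies (10 label permutations by
default, 1000 bootstrap draws): it brackets where a null accuracy falls,
which is the band plotted against the real accuracy time course. A
confidence interval of the shuffled *mean* would be exited by null data most
of the time and cannot reproduce the figure-level behavior; with few
permutations the distribution band slightly undercovers (~90 % rather than
95 %), which the tests account for.

ROI subsampling draws up to 50 unique pseudorandom subsets per size (capped
at the number of distinct subsets), seeded.

Dimensionality is the participation ratio `(Σλ)²/Σλ²` of the ROI-covariance
eigenvalues, computed over whatever observation axis the caller pools
(full-session frames, or period means across trials); it is `M` for
independent equal-variance ROIs and 1 for rank-one data.

ΔF/F–lick correlations pool (trial, timepoint) pairs within each period —
pre-odorant and odorant windows on all trials, the reinforcement window on
rewarded trials — and report Pearson ρ with its p-value; the derivative
variant differentiates both traces before pooling.

## Encoding model

The design matrix has one row per (trial, frame) within −2…+5.7 s of odor
onset. Event variables: S+ and S− indicators active during odor application.
Whole-trial variables: accuracy (correct = 1), reinforcement history
(previous trial rewarded = 1), and 20-trial windowed percent correct.
Continuous variables: lick rate, its derivative, body velocity and
acceleration, each low-pass filtered — like the response — with a
Hamming-window FIR of length `round(0.59 s × rate)` applied zero-phase (the
"time constant" convention is ours; the window is symmetric and unit-gain).
The fit is ordinary least squares (identity link, Gaussian noise) on
concatenated trials, with aliased columns dropped via pivoted QR and logged.
By default only proficient-epoch trials enter the fit.

Variance explained per period is the fit's R² restricted to rows in the
pre-odorant, odorant, and outcome (reward + 1.5 s) windows, clipped to
[0, 100] %. Group contributions are leave-group-out: `ΔR²(g) = R²_full −
R²_without_g` per period, negative drops clipped at zero, normalized to sum
to 100 % across groups; when every drop is zero (e.g. a signal-free
pre-odorant window) the contributions are uniform and flagged. Collinear
predictors (licking tracks the S+ odorant in proficient sessions) split
credit under this metric, which is why construction tests use odor-presence
signals that licking cannot reconstruct.

The shared statistics layer: `glm_test` is a linear model with categorical
factors and optional interactions (type-II ANOVA term p-values; for one
two-level factor the F equals the pooled t² exactly); post-hoc pairs use a
two-sided t test when both samples pass an Anderson–Darling normality gate
at α = 0.05 and a Wilcoxon rank-sum otherwise, corrected by
Benjamini–Hochberg step-up with `pFDR` = the largest significant p (0 if
none). Bootstrap CIs of the mean use 1000 resamples and default to the BCa
interval (the convention of the standard `bootci`-style routines), with a
plain percentile option.

## Microcircuit model

The circuit is feedforward: parallel fibers (PFs) excite a superficial SC, a
deep SC and the PC dendrite; the superficial SC inhibits the deep SC; both
SCs inhibit the PC soma; the climbing fiber (CF) excites the PC directly and
reaches the SCs by glutamate spillover with a 10-ms delay, firing a 2-spike
300-Hz burst at the reward on rewarded trials. Because nothing feeds back,
synaptic conductances are precomputed by convolving presynaptic event trains
with double-exponential kernels and the membranes are integrated afterwards.

Synapses are normalized double exponentials, `g(t) ∝ exp(−t/τ_d) −
exp(−t/τ_r)` scaled so the peak equals the tabulated peak conductance
(α-function limit at equal time constants): PF–SC 1.3774 nS (τ 3.45/3.17 ms,
E 0 mV), PF–PC 0.2857 nS (0.28/1.23 ms, 0 mV), SC–SC 1.0786 nS (0.6 ms and
the 5.9–11.3 ms range's midpoint 8.6 ms, −60 mV), SC–PC 15 nS (1.8/8.5 ms,
−85 mV, 2 ms delay). Peak conductance × 70 mV driving force reproduces the
tabulated peak currents to <0.1 %. The CF–PC input is the PF–PC synapse
with a ×50 gain ("strong AMPA activation"); CF–SC spillover uses the PF–SC
synapse with a ×5 gain (declared).

The SC is a single compartment whose area is set from the passive targets:
`R_m = 20 kΩ·cm²`, `C_m = 1.5 µF/cm²`, target input resistance 571.39 MΩ ⇒
area ≈ 3.5×10⁻⁵ cm², giving a passive τ_m of 30 ms. The printed 40.3-ms time
constant comes from a double-exponential fit to a reconstructed morphology
and is deliberately not matched — a single compartment cannot have both the
target R_in and that τ_m with these specific parameters. Active currents are
Na, delayed-rectifier K, A-type K and low-threshold Ca with
interneuron-style kinetics (temperature factor 5) tuned only to the
qualitative firing assertions in the tests: silent at rest, repetitive
low-CV firing under sustained depolarization, Ohmic R_in within 1 % in the
passive configuration. The cited channel schemes are not published as
equations, so the kinetics here are standard forms, not a reimplementation.

The PC is two compartments: a soma with Na/KDR spike currents plus a bias
current standing in for intrinsic pacemaking (tonic ~45 Hz under background
inhibition; monotone f–I; silenced by strong GABAa trains), and a passive
dendrite receiving the excitatory synapses, coupled by a 15-nS axial
conductance (derived from `R_i = 115 Ω·cm` over a trunk-scale geometry).
Integration is fixed-step midpoint (RK2) at Δt = 0.025 ms — forward Euler at
this step fails the convergence criterion (halving Δt must change the PC
spike count by ≤1 over 5 s; RK2 changes it by 0).

Learning and chemogenetics are conductance scalings on PF–SC and SC–PC:
learned S+ = 1.0, learned S− = 0.2 ("strong LTD"); under CNO the S+ weight
is reduced by 40 % (0.6) and the S− depression is diminished by the same
fraction (0.2 + 0.4·0.8 = 0.52), both exposed in the scenario config. The
"40 % reduction in SC population activity" is a tonic DREADD-like K⁺
conductance (reversal −90 mV, 0.15 nS) calibrated to cut the baseline-drive
SC rate by ~40 %; a probabilistic spike-deletion alternative is selectable.
A GABAa-reversal (−60 mV) shunt was tried first and barely affects firing at
depolarized potentials, which is why the K⁺ reversal is the default.

Licking is read out as `max(0, L0 − gain·(PC spike train ⊛ Gaussian))` with
a 50-ms-SD kernel; the gain is calibrated per simulation so baseline PC
firing maps to a near-zero (0.5 Hz) lick rate, and lick strength is the mean
lick rate over the odor window. PF drive (20 fibers, 0.5 Hz baseline,
1.5 Hz during odor, aggregate Poisson) and the PC bias are calibration
values chosen so the four conditions occupy the readout's dynamic range:
saline S+ ≈ 8.9, saline S− ≈ 0.3, CNO S+ ≈ 4.8, CNO S− ≈ 3.3 Hz at the
default seed — the ordering and attenuated divergence that the replicated
valence × drug comparison tests at 22 repetitions per condition. Reward-
magnitude effects on licking are intentionally absent, as in the source
model.

## Problem sizes and numerics

Test and acceptance runs use desk-scale inputs chosen as the smallest sizes
at which the stochastic tolerances are comfortable: 80–120-trial sessions
with 10–50 ROIs, 10–20 label shuffles, 1000-draw bootstraps (2000
simulations for the coverage study), 3.5-s circuit trials at Δt = 0.025 ms
and 22 replicates per circuit condition. Seeds are explicit everywhere;
identical configurations and seeds give bit-identical sessions and
simulations. Degenerate inputs (zero variance, empty pools, missing marks,
saturated models) raise or return flagged values rather than NaNs leaking
downstream.

## Known limitations

* The generator's equal-variance latent construction makes dimensionality
  exactly controllable but caps per-ROI signal-to-baseline contrast; real
  sessions have a dominant first eigenvalue and larger responsive fractions.
* The encoding model is for the ensemble-mean trace only (per-ROI encoding
  is out of scope), and the leave-group-out contribution metric splits
  credit between collinear groups.
* The circuit is a minimal three-neuron sketch: no basket cells, no
  morphology, rate-coded lick readout, plasticity as static scalars rather
  than a learning rule. It reproduces orderings and interactions, not
  quantitative firing statistics.
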