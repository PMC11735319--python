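# Methods

`popdyn` re-implements, as a tested library, a population-analysis workflow
for head-fixed two-spout sucrose-preference sessions with simultaneous
basolateral-amygdala (BLA) and ventral-hippocampal (vCA1) Neuropixels
recordings, together with a synthetic-cohort generator that stands in for
the in-vivo data. This note documents the models, the choices we made
where the design was genuinely open, and what the synthetic cohorts do and
do not establish.

## Behavioural model

Reward choices are modelled as a first-order Markov chain over
{water, sucrose}; a 2×2 row-stochastic matrix per behavioural group fully
specifies the sequence distribution. Transition statistics are estimated
from the (n−1) ordered previous–current pairs of a session (the first
trial has no predecessor and is discarded), normalized per previous reward
so that P(WW)+P(WS) = 1 and P(SS)+P(SW) = 1, with chance-removed pair-type
proportions obtained by subtracting the joint probability of the marginal
choice frequencies (these may legitimately be negative and are kept
signed).

The lick discrimination index (DI) is the mean, over the two choice types,
of (lick rate on the sucrose spout − lick rate on the water spout) in a
window; it is antisymmetric under relabelling the spouts and zero when
licking ignores spout identity. All licks inside the window count; the
analysis does not separate sampling from consummatory licks, since the
lick stream carries no such annotation.

Stress subtypes are recovered by K-means on (sucrose preference,
social-interaction ratio), with K chosen to maximize the mean silhouette
score over K = 2…10; silhouette ties break toward smaller K and K-means
uses 10 seeded restarts so the labelling is reproducible. The cluster with
the lower mean sucrose preference is called susceptible.

## Hidden Markov models

Spike counts in fixed bins are modelled by a K-state HMM with independent
Poisson emissions per neuron: P(n_t | S_t = j) = Π_i Poisson(n_{it}; λ_{ij}),
with parameters {A, T, E} (initial distribution, transition matrix, N×K
rate matrix). Continuous facial/limb features use diagonal-Gaussian
emissions; full covariance would roughly double the emission parameter
count at the state counts involved and is not needed for the feature
dimensionalities here. Fitting is Baum–Welch EM with a scaled
forward–backward pass, 5 random restarts, at most 100 iterations, and a
relative log-likelihood tolerance of 1e-6; Poisson rates are floored at
1e-6 so silent neurons cannot produce log(0). Model selection minimizes
AIC = 2p − 2 log L with p = (K−1) + K(K−1) plus the free emission
parameters (N·K Poisson, 2·N·K diagonal Gaussian). State paths come from
the Viterbi algorithm with ties broken toward the lower state index.

Trial-aligned fits concatenate trials as separate segments and reset the
forward recursion at each boundary, so no transition probability is spent
across inter-trial gaps. Bin conventions: pre-task analyses use 1-s bins
over minutes 2–8 of the pre-task period (360 bins); switch/stay analyses
use four 1-s bins over the 4-s pre-reward window per trial; all bins are
half-open [t, t+Δ).

Posterior smoothing replaces each bin's observation by the posterior
mixture of state means, Y_t = Σ_j γ_t(j) μ_j (e.g. posteriors (0.2, 0.8)
give Y = 0.2 μ₁ + 0.8 μ₂); smoothed activity always lies in the convex
hull of the state means.

## State geometry and intention-selective states

State activity vectors (columns of the emission matrix) are compared by
Pearson correlation; clustering runs on the distance D = 1 − J with
complete ("farthest point") linkage, and the number of clusters is read
off at fixed distance thresholds (0.1–0.5 for neural states, 0.01–0.05
for face states, whose correlations are much higher).

A state's intention content is the Shannon entropy of its switch/stay
occurrence profile, H = −(P_switch ln P_switch + P_stay ln P_stay) with
0·ln 0 ≡ 0. Occurrence frequencies are normalized per trial type before
forming P_switch so class imbalance cannot masquerade as selectivity. The
log base is immaterial for the selection rule (only H = 0 matters); we use
the natural log. A state is intention-selective iff H = 0, i.e. it occurs
exclusively in one trial type, subject to a minimum-occurrence floor of
3 bins across the session — without a floor, any state observed once
would trivially score H = 0. When states are merged by clustering, a
cluster inherits the union of member-state occurrences before the entropy
test. Where a single "best" threshold is needed, the one yielding the
most intention-selective states is used, smallest threshold on ties.

Trial filtering: a trial carries the intention signature when flagged
states occupy ≥ 3 of its 4 pre-reward bins; `remove` mode drops such
trials, `only` mode keeps exactly them.

## Decoding

Pseudo-populations pool neurons of one region and group across sessions;
a neuron is admitted only with ≥ 8 trials of each previous–current pair
type (WW, WS, SW, SS). Pseudo-trials are assembled with equal counts of
the four pair types, each neuron contributing an independently sampled
trial of the required type (without replacement within a draw), so every
binary target — current reward, previous reward, switch/stay — is
balanced over reward history by construction. Decoding uses a
linear-kernel SVM (C = 1, exposed) per 0.5-s bin with stratified 80:20
splits; an unstratified split would bias the classifier toward the
training majority class and pull signal-free accuracy below 0.5.
Accuracies average over cross-validation draws, then neuron subsamples
(default 60 neurons × 10 subsamples). Significance compares the observed
mean against 2 s.d. of a shuffled-label distribution centred on the
theoretical chance level of 0.5.

Decoding from HMM-smoothed activity first splits each session's trials of
every pair type in half so the train and test pseudo-trial pools draw from
disjoint underlying trials; resampling the same trial into both pools
would let the classifier memorize trial identity and score above chance
with no signal. With K = 1 the smoothed features are constant and
decoding is exactly at chance.

The single-animal group decoder uses a Mahalanobis-like distance: the
Euclidean distance from the test animal to a class centroid divided by
the sample variance of that class's training points projected on the
centroid-to-test direction (the only reading of "variance along the
distance direction" that defines a scalar). Each of 1000 cross-validations
balances the groups by subsampling, holds out one animal, min-max scales
the unbounded features (spike-count mean and s.d.) on the training rows
only (test values clipped to [0, 1]), and assigns by minimum distance;
zero variance along the direction falls back to plain Euclidean distance
with a warning. Feature importance is accuracy drop under
leave-one-feature-out.

The generalization decoder trains a linear SVM on the
susceptible-vs-resilient feature rows (balanced, one animal held out per
CV) and applies each fitted model, unretrained, to the saline/CNO rows;
its null distribution fixes one label permutation per shuffle and averages
held-out accuracy over several CVs, mirroring how the observed mean is
formed (a single-CV shuffle statistic would have s.d. ≈ 0.5 and no power).

Face-at-chance neural decoding balances the training animals per class in
every leave-one-animal-out split (an unbalanced split biases the
classifier against the held-out animal's class), selects test bins whose
face-feature decoding accuracy lies within 2 shuffle s.d. of 0.5, and
repeats group decoding on those bins with per-bin neural summary features
(population mean and s.d. of the spike count).

## Geometry and connectivity

Dimensionality uses PCA of per-neuron z-scored counts on random 5-neuron
subsamples (1000 by default), reporting the mean cumulative-variance
curve, its first three values as decoder features, and the participation
ratio PR = (Σλ)²/Σλ², which is scale-invariant and ranges from 1 (one
dominant dimension) to N (isotropic). Classical MDS diagonalizes the
double-centred squared-dissimilarity matrix; each group's rows may first
be divided by the group variance; negative eigenvalues (non-Euclidean
input) are truncated at zero with a warning, and embeddings are defined
only up to rotation/reflection.

Pre-task inter-regional coupling reduces each region to the PCs covering
90% of variance (capped at 5 — the wording "aligned the first PC by CCA"
is ambiguous between a scalar alignment and a PC-space alignment; the
PC-space reading is the default and degrades gracefully to the scalar
one), fits the first canonical pair, and analyses the cross-correlogram
of the canonical variates over ±50 s lags; the power spectral density is
the squared FFT magnitude divided by the signal length, the dominant
frequency is the non-DC PSD argmax (flagged unstable when the peak is
below twice the median spectral floor), and the grid is bounded by the
Nyquist frequency f_s/2 = 0.5 Hz at 1-s bins. Pre-reward coupling is the
Pearson correlation of the two regions' mean-rate traces per 1-s window
(10-ms bins), Fisher z-transformed with |r| capped at 1 − 1e-6, and
contrasted as z_sucrose − z_water. Intention-state connectivity resamples
5 neurons per region 1000 times, projects each bin class onto its own
leading PCs as denoising, and averages the absolute correlation between
matched PC time courses (PC signs are arbitrary, so signed correlations
would cancel).

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, not
the biophysics. Per group it specifies: the choice-transition matrix;
the number of pre-task hidden states and their target pairwise rate-vector
similarity (each state's rate vector mixes a shared and a private Gaussian
factor so the expected correlation equals the target); a sticky pre-task
state chain (stay probability 0.9, uniform stationary distribution); a
baseline rate of 5 spikes/s; post-reward choice modulation on half the
neurons at depth 0.6; additive sucrose-spout lick excess generating the
DI; and group Gaussians for social-interaction ratio and open-arm time.
Calibration (chosen once): control transitions favour sucrose-stay
(P(S→S) = 0.80, 4 states at similarity 0.55), resilient slightly weaker
(P(S→S) = 0.75, 5 states at 0.45), susceptible favours water
(P(W→W) = 0.75, P(S→W) = 0.60, 8 states at 0.15, blunted lick DI).
Sucrose-stay probabilities are kept moderate so that sessions of ~120–200
trials still contain the ≥ 8 trials of every pair type that the
pseudo-population rule demands.

Intention states are injected at trial granularity: with probability
`intention_state_strength` (0.75 for susceptible, 0 otherwise) a switch
(stay) trial spends its entire 4-s pre-reward window in a switch- (stay-)
exclusive state with its own rate vector. Hidden states are temporally
persistent under sticky dynamics, so trial-level persistence is the
natural generative picture; it also makes the ≥ 3-bin trial filter
coincide exactly with the injected trials, so removing them removes the
signal rather than thinning it. The rescue (CNO) condition sets the
strength to 0 and shifts choices toward sucrose-stay; the same-reward
control makes choices unbiased coin flips and injects no intention
signal. The default cohort mirrors the study design (15 control, ~12
susceptible, ~33 resilient); tests and the pipeline run smaller cohorts.

All randomness flows through one `numpy.random.SeedSequence` per session,
with sub-streams spawned deterministically, so every generator is a pure
function of (parameters, seed).

What passing tests show — and do not. The end-to-end suite demonstrates
that the pipeline recovers the contrasts the generator encodes
(above-chance switch/stay decoding that collapses after intention-trial
removal, a higher intention-state fraction and more dissimilar pre-task
states in the susceptible profile, abolition under rescue) at cohort
sizes of 5 animals/group, 20 neurons and ~160 trials; these sizes keep the
default runs at desk scale. Poisson emissions lack refractoriness, bursting
and slow drift; keypoint streams are smoothed noise around a fixed
geometry; and no biological claim follows from recovering a signal the
generator injected — the tests validate the estimators and their
calibration, not the in-vivo findings.

## Numerical conventions and limitations

Time is in seconds, session-relative; bins are half-open. EM is
guaranteed non-decreasing only up to the 1e-8 tolerance used in tests
(parameter floors can cost strictly monotone steps). auROC uses the rank
formulation (ties count ½) and selectivity is two-sided (a bin is
selective when its auROC leaves the shuffle mean by more than 2 s.d. in
either direction), with whole-trial label permutation; the shuffle s.d.
from 10 shuffles is noisy, and `n_shuffles` is exposed. The face→neural
ridge R² is reported both in-sample and by 5-fold cross-validation.
Viterbi ties, silhouette ties and threshold ties are all broken
deterministically as stated above. The pipeline orchestrator records
per-stage failures and skips dependents instead of aborting; identical
(config, seed) runs produce identical results archives.
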