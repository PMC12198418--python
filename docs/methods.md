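# Methods

This note documents the models, estimators and design choices implemented
in `oscroute`, and what the synthetic data generator does and does not
emulate.

## Scientific setting

During visuospatial working-memory tasks, MEG amplitude envelopes at theta
(6 Hz) and alpha (10 Hz) organize into a small set of large-scale cortical
networks (posterior and dorsal, in each band). At any moment one network
dominates, defining a brain state; subjects switch between states, and the
statistics of those switches relate to task performance. The package
implements (1) the analysis pipeline that extracts these networks and
states from parcel-level envelope data and computes the associated
statistics, and (2) a dual-layer whole-brain model in which a slow
oscillatory layer routes fast spiking activity by phase-amplitude gating,
used to ask how network synchronization shapes information flow.

## Envelope pipeline

**Morlet envelopes.** Parcel time series are convolved with complex Morlet
wavelets (5 cycles) at the band center frequency; the envelope is the
magnitude of the complex coefficient. Envelopes are downsampled to five
samples per carrier cycle (50 Hz for alpha, 30 Hz for theta) — by plain
decimation when the ratio is integer (the wavelet is the anti-alias
filter), otherwise by polyphase rational resampling. Half the wavelet
support is trimmed from each trial edge by default.

**Normalization.** Envelopes are z-scored pooled over parcels and time
within each (frequency, session, subject, task) group. Pooled rather than
per-parcel scoring is deliberate: it equalizes groups while preserving the
relative parcel loadings that spatial ICA separates on. Per-group scoring
is the only option implemented; a zero-variance group is an error.

**Spatial ICA.** FastICA on (trial x time) samples with parcels as
features, 2–5 components, 20 seeded restarts keeping the run with the
highest log-cosh negentropy surrogate among converged runs. The unmixing
rows are the network weight vectors; each is sign-flipped so its weight sum
is nonnegative, and components are ordered by back-projected variance.
Components are matched to reference templates by greedy one-to-one
assignment on |cosine|; a best match below 0.3 is declared unidentifiable.

**Brain states.** K-means (Euclidean, K = 4 by default, 50 restarts, fixed
seed) on the per-timepoint component activations. States are relabelled so
state j is the one whose centroid peaks on component j; ties fall back to a
greedy assignment with a warning. Switch counting is the number of
consecutive-label changes at the envelope sampling rate, with no debouncing.

**Statistics.** Paired and pooled-variance independent t-tests with Cohen's
delta (paired: mean/sd of differences; independent: pooled sd), standardized
OLS (z-scored dependent and independent variables), one-sided CIs reported
as [lower, inf), and Benjamini–Hochberg FDR. The quadratic
switch-performance and load regressions report the raw-unit vertex
(-b1/2b2) as the optimum. The distractor contrast signs each stimulus
window by its expected direction, averages windows within subject, and
applies a one-sided paired t-test.

## Dual-layer model

Each of the 202 nodes (200 cortical + one basal-ganglia-thalamus node per
hemisphere) carries a Kuramoto phase and a spike rate, coupled over the
same structural graph with distance-proportional conduction delays:

- phases: dtheta_n/dt = omega + k * sum_p C_np sin(theta_p(t - tau_np) - theta_n(t)),
  with omega = 0.04*2*pi rad/ms (40 Hz), k = 0.22, additive Gaussian phase
  noise of variance 0.0025 per Euler step, dt = 0.1 ms;
- rates: du_n/dt = w * sum_p C_np û_p(t - tau_np) - a u_n(t) + I_n(t),
  with w = 0.8, a = 0.25 /ms; I_n = 1 stimulates node n (sustained by
  default, windowable);
- gating: m_n(t) = -0.5 sin(theta_n) + 0.5 in [0, 1]; the gated rate is
  u_pac = u * m (spiking enhanced at oscillation troughs, suppressed at
  peaks), and by default the transmitted rate û is the gated rate, so the
  oscillatory layer physically routes spiking activity. A literal
  integrated-ODE gating variant and raw-rate transmission are available
  behind flags.

C is normalized so incoming weights per node sum to one, in both layers.
Delays are tau = round(2 * D_mm) in integration steps, i.e. 0.2 ms/mm —
with realistic inter-region distances this yields a mean node-to-node
travel time of ~20 ms; the alternative reading (2 ms per mm) would give
implausible ~200 ms delays and is rejected. Phase noise is applied with the
stated variance per step without sqrt(dt) rescaling, because the variance
is specified jointly with the fixed dt; results are therefore
dt-reproducible only at dt = 0.1 ms. Initial phases are uniform, rates
zero, and the phase history is backfilled at the natural frequency.

A note on stability: with incoming-normalized C the spiking layer's
effective gain (w times the mean gate, 0.4) exceeds the leak a = 0.25, so
any stimulated run grows exponentially. This is a property of the stated
parameters, not a bug; the information-flow readouts are scale-free
(z-scored and binned), and all comparisons are paired across conditions
with matched noise.

**Thalamic drive.** Synchronization of a cortical network is induced by
multiplying the oscillatory-layer weights from the subcortical nodes into
the target mask by a gain and retuning the subcortical natural frequency to
the drive frequency (6 or 10 Hz). The gain default (4) was calibrated once
on the default synthetic connectome so the within-mask PLV contrast lands
on the ~60% scale; it is exposed as a parameter.

## Synchronization and information flow

**PLV.** plv = |mean_t exp(i(theta_a - theta_b))|; the imaginary variant
takes |Im| of the mean phasor, discarding zero-lag locking. The
synchronization contrast of a mask is the mean pairwise PLV among mask
nodes versus among non-mask cortical nodes, reported as an absolute and a
percent difference.

**Transfer entropy.** Series are z-normalized per node, mapped affinely to
21 integer levels (0..20), and for each delay Delta in 1..400 steps
(0.1–40 ms) the triple histogram of (a(t), b(t), b(t+Delta)) yields

    dTE(Delta) = sum p_abD * log(p_abD / (p_ab * p_bbD)),

summed over delays. This delayed co-information form equals
I(a; b(Delta) | b) + H(b): it is nonnegative and carries the target's
marginal entropy in addition to the directed term. It is implemented
exactly in this form (an independent triple-loop oracle pins it down in the
tests); a canonical conditional (Schreiber-style) estimator is available as
`method="conditional"` and is kept strictly separate. Empty histogram cells
contribute zero; constant series define TE = 0 with a warning. Estimates
carry positive small-sample bias, quantified by permutation surrogates of
the source series. TE is computed on the gated rates by default.

**Routing experiment.** The drive-routing protocol is a 2 x 2 within-seed
design: hub nodes of the posterior and the dorsal network are stimulated
under matching and non-matching drive with identical noise, and each
source's total TE outflow to all other cortical nodes is computed. Total TE
carries a run-level component — the gating field of a drive condition
shifts every estimate in that run — so the routing effect is read out as
the within-seed interaction (matching minus non-matching, averaged over
sources of both networks), which cancels the shared field term exactly as a
within-subject interaction contrast does; a one-sided paired t-test across
seeds then asks whether matching drive increases outflow. Per-node
frequency contrasts (theta vs alpha drive) use paired t-tests per target
node with BH-FDR across nodes.

## Synthetic data

**Envelope cohorts.** K unit-norm nonnegative spatial networks on disjoint
parcel blocks; a sticky Markov chain (stay probability 0.9) over K hidden
states; per-network activations are exponentiated smooth Gaussian noise
(lognormal, heavy-tailed — the non-Gaussianity ICA needs and a reasonable
stand-in for envelope skewness) multiplied by a state gain (default 3) when
the state's network dominates. Envelopes are the mixture plus truncated
Gaussian noise (default sd 0.1), nonnegative by construction. Ground truth
(weights, labels, activations) lives in a metadata sidecar that no pipeline
stage reads. Default cohort for the analyses: 4 subjects x 10 trials x 60
parcels x 3 s at 50 Hz — large enough for reliable ICA recovery, small
enough to run in seconds.

**Connectomes.** Cortical nodes on two hemispheric spherical shells
(radius 75 mm), seven named subcortical regions per hemisphere clustered
near the midline. Connection weights decay as exp(-0.04 * D_mm) with
symmetric lognormal jitter — streamline counts are short-range dominated —
plus a subcortical hub factor (3) and a within-module boost (3) on the
posterior and dorsal masks, reflecting that the functional networks ride on
structurally coupled modules; without modular structure the graph is
effectively complete and gating has no paths to select between. Masks are
the most posterior and most superior cortical nodes (20% each). The
collapsing step drops amygdala and hippocampus and sums the remaining five
regions per hemisphere into one BG-thalamus node (weights added, distances
strength-weighted averaged).

**What the generator does not emulate:** source leakage and volume
conduction, 1/f background spectra, inter-subject anatomical variability,
task-locked transients, or tractography biases. Passing recovery tests
therefore demonstrates the correctness and sensitivity of the estimators
under the assumed generative structure, not performance on real MEG.

## Problem sizes

The analyses and acceptance checks run at desk scale by choice: routing
uses a 42-node collapsed connectome (40 cortical + 2 BG-thalamus), 2 s per
run (0.5 s burn-in), 10 matched seeds, TE over the full 400-step delay
range; the full 202-node graph is exercised by the connectome-construction
analysis and supported by the same integrator. The envelope cohort is 4 x
10 x 60 parcels.

An honest caveat on the routing readout: the synchronization side is
robust — thalamic drive raises within-mask PLV above outside-mask PLV in
every seed tested — but the transfer-entropy interaction is not systematic
at this scale. The default 10-seed protocol yields a positive contrast
(8/10 seeds, one-sided p = 0.03, d = 0.65), yet a 30-seed replication at
fresh seeds centers on zero (mean -0.2, sd 114, 15/30 positive). At 42
nodes and 2 s per run, seed-to-seed fluctuations of the binned TE estimate
are as large as any routing signal the gating produces; whether the
direction emerges systematically at the full 202-node, multi-connectome,
longer-duration scale is left open rather than claimed.

## Known limitations

- The co-information TE includes H(target); between-condition comparisons
  therefore mix directed-coupling changes with target-entropy changes. The
  conditional estimator isolates the directed part.
- The spiking layer's exponential growth means late-time samples dominate
  the binned histograms on long runs; analysis windows are kept moderate.
- ICA component count selection (2–5) is left to the caller; the
  explained-variance ordering makes truncation explicit rather than
  automatic.
- The k-means state labelling assumes each component dominates exactly one
  centroid; degenerate centroid patterns fall back to greedy assignment
  with a warning.
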