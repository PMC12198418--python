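# oscroute

Oscillatory brain-network states and phase-gated information routing.

During visuospatial working-memory tasks, MEG amplitude envelopes in the
theta (6 Hz) and alpha (10 Hz) bands organize into a handful of large-scale
cortical networks — posterior and dorsal, in each band. At every timepoint
one network dominates, defining a brain state; the switching dynamics
between states tracks cognitive performance. `oscroute` implements this
analysis pipeline end to end, plus the mechanistic counterpart: a dual-layer
whole-brain model in which slow Kuramoto oscillations gate fast spiking
activity through phase-amplitude coupling on a structural connectome, used
to test whether network synchronization routes information flow.

The package is organised as an analysis project: the computation lives in
`src/oscroute`, and numbered drivers under `analysis/` walk through the
study (synthetic cohort -> networks and states -> behavioural statistics ->
model connectome -> routing simulations -> frequency contrast), writing
their tables to `results/`.

## What is implemented

| module | contents |
| --- | --- |
| `oscroute.syndata` | synthetic envelope cohorts with planted networks and hidden Markov states; synthetic connectomes with posterior/dorsal modules and subcortical hubs |
| `oscroute.spectral` | 5-cycle complex Morlet envelopes, downsampling to 5 samples per cycle, group-pooled z-normalization |
| `oscroute.networks` | per-subject spatial FastICA, cosine-similarity comparison, template matching, reliability analysis across sessions/tasks/subjects |
| `oscroute.states` | k-means brain states (K=4) with dominance relabelling; occupancy, switch counts, time-in-state; switch-performance and load regressions, PC1 composite, distractor contrast |
| `oscroute.connectome` | 214 -> 202-node subcortex collapsing, incoming-weight normalization, distance-to-delay conversion (0.2 ms/mm) |
| `oscroute.simulator` | Euler–Maruyama integration of the delayed Kuramoto layer (omega = 0.04·2π/ms, k = 0.22, noise var 0.0025, dt = 0.1 ms) coupled to a spike-rate layer (w = 0.8, a = 0.25) through the phase gate m = −0.5 sin θ + 0.5; thalamic drive and stimulation |
| `oscroute.infoflow` | PLV / imaginary PLV, mask synchronization contrasts, delay-summed transfer entropy (21 bins, delays 1–400 steps) with an optional conditional variant, permutation surrogates, per-node FDR-corrected contrasts |
| `oscroute.stats` | paired/independent t-tests with Cohen's delta, standardized OLS, Benjamini–Hochberg FDR |
| `oscroute.experiments` | the 2×2 drive-routing protocol and the theta-vs-alpha frequency contrast |

The model core, in the field's notation: phases follow
dθₙ/dt = ω + k Σₚ Cₙₚ sin(θₚ(t−τₙₚ) − θₙ(t)), rates follow
duₙ/dt = w Σₚ Cₙₚ ûₚ(t−τₙₚ) − a·uₙ + Iₙ, and the transmitted rate is
ûₙ = uₙ·(−0.5 sin θₙ + 0.5). Transfer entropy from a to b is the
delay-summed co-information Σ_Δ Σ p(a,b,b_Δ) log[p(a,b,b_Δ)/(p(a,b)p(b,b_Δ))]
on 21-level binned series. See `docs/methods.md` for assumptions,
parameter meanings and numerical choices.

## Worked example

```python
import numpy as np
from oscroute.syndata import EnvelopeSpec, generate_cohort
from oscroute.spectral import normalize_envelopes, EnvelopeArray
from oscroute.networks import extract_components, match_components, cosine_similarity
from oscroute.states import cluster_states, count_state_switches

spec = EnvelopeSpec(n_subjects=1, n_trials=10, n_parcels=60,
                    trial_duration=3.0, seed=1)
env, true_states = generate_cohort(spec)
envn = normalize_envelopes(env)
comps = extract_components(envn, n_components=4, seed=0)
W = env.metadata["planted_weights"]
matched = match_components(comps, {j: W[j] for j in range(4)})
print([round(abs(cosine_similarity(matched[j].weights, W[j])), 3)
       for j in range(4)])
tc = np.stack([matched[j].timecourse.mean(axis=0) for j in range(4)], axis=1)
model, seq = cluster_states(tc, K=4, seed=0)
print(int(count_state_switches(seq)[0]))
```

prints

```
[0.995, 0.996, 0.996, 0.998]
13
```

— the four planted spatial networks are recovered almost exactly (|cosine|
to ground truth above 0.99), and the clustered state sequence switches 13
times over the 3-s trial window, i.e. the k-means states track the sticky
hidden Markov chain (which switches rarely) rather than noise.

Running `python analysis/05_drive_routing.py` simulates the four
drive/stimulation conditions on the synthetic connectome and prints the
within-mask synchronization contrast (on the order of tens of percent,
positive in every seed) and the paired transfer-entropy outflow contrast
between matching and non-matching drive, with its one-sided p-value.

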