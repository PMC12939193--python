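# Methods

## Pipeline

Each scan is a T × N matrix of parcel-averaged BOLD signal (TR in
seconds; N = 90 for AAL-90 data). The per-scan reduction is:

1. **Preprocessing.** Columns are demeaned and linearly detrended
   (least-squares). When a band is given, a second-order Butterworth
   band-pass (0.01–0.08 Hz by default) is applied forward–backward
   (`sosfiltfilt`), so the effective magnitude response is the square of
   the prototype's and the phase response is zero — zero phase matters
   because the next step estimates instantaneous phase. `band=None`
   skips filtering for inputs that are already band-limited.
2. **Instantaneous phase.** θₙ(t) is the argument of the analytic
   (Hilbert) signal of column n. An all-zero column raises an error: its
   phase is undefined.
3. **Phase coherence.** C(t) = ccᵀ + ssᵀ with c = cos θ(t), s = sin θ(t),
   i.e. C(t)ₙₚ = cos(θₙ − θₚ). C is symmetric PSD with unit diagonal,
   rank ≤ 2, and λ₁ + λ₂ = N; adding a constant to all phases leaves it
   unchanged.
4. **Leading eigenvector.** Because the non-null eigenvectors of C lie in
   span{c, s}, the per-volume eigenproblem reduces to the 2 × 2 Gram
   matrix [[c·c, c·s], [c·s, s·s]], solved in closed form and mapped back
   (this is the production path; a dense symmetric solver backs the
   generic `leading_eigenvector` and serves as the oracle in tests).
   The sign is fixed by: flip so Σₙvₙ > 0; if |Σₙvₙ| < 1e-12, flip so
   the largest-magnitude element is positive. This makes the fully
   coherent pattern all-positive and is idempotent and deterministic.
   If λ₁ − λ₂ < 1e-10·N the top eigenspace is degenerate; a warning is
   emitted and the solver's first vector is kept.
5. **Edge trimming.** The first and last volume are dropped (Hilbert
   boundary transients), so a T-volume scan contributes T − 2
   eigenvectors. Coherence matrices are formed per volume and never
   materialized scan-wide, so memory scales with N², not T·N².

## Clustering

Eigenvectors pooled across scans are partitioned by k-means under the
cosine distance for each K in 2…20. Rows and centroids are unit norm, so
the centroid update is the normalized mean of assigned rows (spherical
k-means). Each of the 25 default replicates draws K distinct rows
uniformly at random (per-replicate seeded stream) as initial centroids;
Lloyd iterations stop when the assignment stabilizes or after 300
iterations; the lowest-inertia replicate wins. An empty cluster is
re-seeded from the row farthest from its current centroid
(deterministic). Assignment ties go to the lowest state index. States
are sorted by descending occupancy (stable on ties) and relabelled 1…K;
centroids are sign-canonicalized with the eigenvector rule (a no-op in
practice, since canonicalized rows have positive sums and so do their
means). The family over K = 2…20 contains Σ K = 209 states.

Centroid-to-network matching is a Pearson correlation against
user-supplied named reference vectors, reporting the argmax or "none"
below r = 0.3. The packaged 7-network reference set is synthetic (block
patterns); mapping a real atlas to a parcellation is out of scope.

## Occupancy metrics and inference

Fractional occupancy is computed per scan (FO rows sum to 1 within each
solution); dwell time is the mean length of maximal consecutive runs of
a state times TR, counting boundary-truncated runs in full (flagged NaN
for unvisited states); switching rate is transitions per second. Group
statistics always operate on scan-level values.

The per-state test permutes scan-level group labels with the difference
of group means as the statistic, two-sided. When C(n₁+n₂, n₁) ≤ the
permutation budget the null is enumerated exhaustively and the exact
proportion reported; otherwise the Monte-Carlo estimate uses add-one
smoothing, (1 + b)/(1 + n_perm), so p = 0 cannot occur. Each state gets
an independent stream derived by hashing (master seed, K, state).
Effect size is Hedges' g = J·(m₁ − m₂)/s_pooled with J = 1 − 3/(4n − 9),
with the normal-approximation 95% CI g ± 1.96·√(n/(n₁n₂) + g²/2n).
Significance tiers: `global` if p < α/(total states across all K, 209
for K = 2…20), `within_K` if p < α/K, `nominal` if p < α, else `ns`.
No covariate adjustment or site harmonization is performed.

## Synthetic cohorts

The generator emulates a two-group parcellated resting-state study in
which S spatial phase configurations recur under Markovian switching.
Regions are partitioned into S disjoint communities (~N/S each).
While state s is active, community regions follow
cos(2π f t·TR) and all others cos(2π f t·TR + φ) with separation
φ = π/2 by default (placing out-of-community regions at the cos = 0
boundary of the coherence measure); f is a per-subject carrier drawn
uniformly from (0.02, 0.06) Hz; i.i.d. Gaussian noise (σ = 0.2, against
unit carrier amplitude) is added. Switching is a per-volume hidden
Markov chain — states are defined per TR — from the family
P = ρI + (1−ρ)·1πᵀ, which has stationary distribution exactly π and
stickiness ρ (default 0.6: mean dwell ≈ 3.3 volumes ≈ 6.7 s at TR = 2 s,
in the range reported for empirical PL states). Two groups differ only
in π: `occupancy_shift_models` raises one state's stationary probability
by a configurable gap in group B. Transitions switch offsets
instantaneously, keeping ground-truth labels exact.

At separation π/2 the noiseless coherence matrix of state s is the sum
of two within-block all-ones matrices, so its leading eigenvector is the
indicator of the larger block — the community's complement. Templates
are therefore built with only 1% of their squared norm on the (positive)
community and 99% on the (negative) complement, so each template is
nearly (anti-)parallel to the eigen-direction its own phase pattern
produces; a small multiplicative jitter (±10%) breaks exact symmetry.
Recovery comparisons use |cosine| throughout, since eigenvector sign
canonicalization can flip orientation relative to a template.

Synthetic cohorts are analysed with `band=None`: their deterministic
signal content is band-limited by construction, matching the situation
of consortium releases whose band-pass belongs to preprocessing, with no
further filtering before the phase step. (Re-filtering such data is
harmless for real, smoothly varying signals but visibly smears the
instantaneous phase around this generator's idealized instantaneous
transitions; the filter's own contract — passband flatness, stopband
attenuation — is tested directly on raw sinusoids.)

What the generator does **not** emulate: hemodynamic convolution,
1/f noise, scanner/site effects, motion, spatially graded phase
patterns. Passing tests demonstrate correctness of the machinery and
calibration of the inference under exchangeable nulls, not performance
on real fMRI.

## Test and demonstration scales

Unit and property tests run on cohorts of 2–10 scans with 40–200
volumes. The calibration suite uses 200 null cohorts of 20 + 20 scans
(T = 120, K = 2…5, 1000 permutations) and checks the per-state rejection
rate against the 99% binomial band around α = 0.05. Power/recovery runs
use 20 cohorts of 40 + 40 scans (T = 200, K = 4, stationary gap 0.05).
The acceptance script sweeps the full K = 2…20 pyramid on one 40 + 40
cohort with 10 k-means replicates per K and 5000 permutations per state.
These sizes are the package's chosen demonstration scale — large enough
for stable calibration and ≥ 80% power at the planted effect, small
enough to run on a laptop in minutes.

## Numerical choices and edge cases

- Seeds: every stochastic stage derives its seed by SHA-256 hashing of
  (master seed, stage tokens), so runs are bit-reproducible and streams
  are independent; all derived seeds are < 2³¹.
- Permutation tie handling: permuted |statistics| within 1e-12 of the
  observed one count as exceedances.
- Zero pooled variance in Hedges' g: g = 0 when the means are equal,
  an error otherwise.
- k-means with K exceeding the number of distinct rows, labels outside
  1…K, ragged region counts across a cohort, unknown group tokens, and
  unknown config keys all raise descriptive errors; analysis configs are
  flat key-value YAML with unknown keys rejected (silent typos in
  analysis configs are a known hazard).
- `dwell_times` returns NaN for unvisited states rather than 0, so
  downstream averaging cannot silently mix "absent" with "brief".
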