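# Methods

## The model

`gutflow` implements a coarse-grained consumer–resource model of the lower
gut. Metabolites enter as a nutrient intake vector **c**. The community is
described by a bipartite capability network: which species can consume
which metabolites, and which they can secrete as byproducts. The flow is
discretized into trophic levels; one level is one round of consumption and
byproduct generation.

At each level:

- Every consumable metabolite (one with at least one present,
  positive-abundance consumer) is split across its consumers in proportion
  to abundance × uptake rate. The uptake matrix `A_in` (species ×
  metabolite) is column-stochastic on consumable columns:
  `(A_in)_{α,i} = κ_i λ_{α,i} B_α` with `κ_i = 1 / Σ_α λ_{α,i} B_α`.
- A fraction `1 − f` of what a species consumes becomes its biomass; the
  byproduct fraction `f` is secreted, split across the species' producible
  byproducts by the column-stochastic secretion matrix `A_out` (equal
  split `1/N_out(α)` by default; explicit or Dirichlet-drawn weights are
  supported).
- Metabolites nothing present can consume are set aside; after the final
  level they, together with the last level's byproducts, form the
  predicted fecal metabolome **M**.

Biomass accumulated by a species over all levels is summed, and biomass and
metabolome are normalized separately into relative profiles. Abundances
inside `A_in` are the measured ones at every level; the model does not
update them dynamically (no ODEs, no chemostat, no spatial structure, no
host or pH effects).

Two printed closed forms for the per-level biomass and byproducts carry
exponents inconsistent with the level-one equations they generalize; the
implementation treats the iterated recursion as canonical and uses the
exponents `b_ℓ = (1−f) f^{ℓ−1} A_in (A_out A_in)^{ℓ−1} c` and
`c_ℓ = f^ℓ (A_out A_in)^{ℓ−1} · (A_out A_in applied once more at each
step)`, which agree with the recursion everywhere (the equivalence is
asserted to 1e-10 in the tests).

### Accounting choices

- **Sink.** A species with no recorded byproducts still consumes; its `f`
  fraction has nowhere to go. It is routed to an explicit sink
  accumulator, reported per level and excluded from the metabolome, so
  that `Σ biomass + Σ metabolome + Σ sink = Σ intake` holds to 1e-9
  relative — the package's master invariant, tested on random instances.
- **Unknown intake metabolites.** Intake entries absent from the network
  vocabulary pass through to the metabolome at level 1, the natural
  generalization of "unconsumable in this sample".
- **Consumability is per sample**: a metabolite with consumers in the
  database but none present (at positive abundance) in the sample is
  unconsumable there.
- Metabolite amounts are compared in measurement units; no molecular-
  weight normalization.
- The cascade is **linear in the intake** at fixed abundances. The fitter
  exploits this by precomputing the biomass operator `L` (one cascade per
  intake basis vector) so that each objective evaluation is a small
  matrix–vector product. This is an exact reformulation.

## Intake inference

The intake is unmeasured and is inferred per sample: bounded non-negative
least squares (`scipy.optimize.least_squares`, trust-region reflective,
analytic Jacobian) on the residual vector
`log10(max(p_α, ε)) − log10(max(m_α, ε))` over the sample's mapped,
positive-abundance species, with floor `ε = 1e-6` (species unreachable
from the intake predict exactly zero biomass; the floor keeps the
objective finite). Starts are drawn uniform(0, 1) per component and
normalized; 10 restarts by default (the objective is non-convex in log
space); the best restart is kept. Because the predicted relative profile
is invariant to the intake scale, the fit runs over free non-negative
amounts and the result is renormalized to the simplex. Observed species
that do not map into the network are dropped and the remainder
renormalized before fitting.

## Calibration

The predicted metabolome is compared with a measured one over the matched
metabolite ids, both renormalized over the matched subset (predictions are
relative; measured units are instrument-specific), floored and
log10-transformed. Scores: Pearson r; a one-tailed P-value with the
t statistic divided by `sqrt((n−2)/(n−2−p))` and referred to Student-t
with `n − 2 − p` degrees of freedom, `p = 2` for the two fitted global
parameters; and the logarithmic accuracy (mean |log10 p − log10 m|, the
order-of-magnitude error). Grid search over
f ∈ {0.1, …, 0.9, 0.95, 0.99} × N ∈ {2, …, 10} (configurable) fits every
sample's intake per cell, aggregates mean r, median adjusted P and mean
log accuracy, and reports the argmax-r cell (argmin log accuracy
alongside).

## Null models and robustness variants

- **Capability shuffle**: degree-preserving double-edge swaps, applied
  independently to the consumption and production edge sets; attempted
  swaps = 3 × |E| per set, swaps that would duplicate an edge are rejected
  and count as attempts. Both bipartite degree sequences are preserved
  exactly.
- **Label shuffle**: species names permuted; capability pairs travel
  intact.
- **Random uptake rates**: λ i.i.d. uniform(0, 1) on consumption edges.
- **Dirichlet secretion**: per-species secretion weights from a symmetric
  Dirichlet over the species' byproducts; concentration defaults to 1
  (flat) — the limit of large concentration recovers equal split.
- **Enzyme budget**: λ = 1/|consumables(α)|, so each species' total uptake
  capacity is 1 (generalists penalized per nutrient).
- **Bootstrap**: cohorts resampled with replacement at original size, for
  re-running the calibration grid.

All are seed-deterministic; consumption/production shuffles use
independent substreams spawned from the seed.

## Level-resolved diversity

Per level ℓ and sample j, the relative contribution `p_i(ℓ, j)` of each
entity is computed (species: biomass increments of that consumption step;
genera: species contributions summed by genus first; metabolites: the
per-level profile in one of three modes — `entering` (default; level 1 is
the intake itself), `produced`, or `unconsumed`). Then

- `D_α(ℓ) = 1 / ⟨Σ_i p_i(ℓ,j)²⟩_j` (inverse Simpson, averaged over
  samples with activity at that level),
- `D_γ(ℓ) = 1 / Σ_i p̄_i(ℓ)²` with `p̄` the cross-sample mean profile,
- `D_β = D_γ / D_α ≥ 1` (Jensen).

No finite-sample correction is applied. Microbial contributions are
indexed internally by consumption step and labelled step + 1 in outputs,
so metabolites occupy level 1 and microbes first appear at level 2.
Dominant-level assignment takes, per entity, the argmax over levels of its
cross-sample mean contribution; ties break toward the earlier level and
are flagged.

## Synthetic ground truth

The generator emulates the study design without any external data: a
random bipartite capability network (defaults: 80 species in genera of 4,
120 metabolites, mean consumption and production degree 2, 19 designated
intake metabolites), per-sample true intakes from a symmetric Dirichlet,
random species presence masks, and log-normal observation noise in dex on
abundances (`σ_abund`) and metabolome (`σ_metab`) applied through an RNG
substream independent of the structural draws (so noise settings do not
alter the community structure at a given seed).

Two design choices matter and were made deliberately:

- **Intake specialists.** Each designated intake metabolite has exactly
  one dedicated consumer. Because uptake columns are normalized, a sole
  consumer receives its metabolite's entire flux regardless of abundance,
  so these species always persist and the intake-to-biomass operator has
  full column rank. Without this, distinct intake metabolites frequently
  share their whole surviving consumer set, their operator columns
  coincide, and the true intake is not identifiable even from noiseless
  data — recovery experiments would measure an ill-posed problem rather
  than the fitter.
- **Fixed-point abundances.** The cascade weights uptake by measured
  abundances, but in synthesis the abundances are themselves model
  output. The generator iterates `abundances → normalized predicted
  biomass` to convergence (tolerance 1e-15, relative extinction threshold
  1e-10; the map behaves like replicator dynamics, so species sharing a
  niche with fitter competitors go extinct and roughly half the seeded
  species survive). At the stored abundances the forward model reproduces
  them exactly at the true intake, which makes noiseless intake recovery a
  well-posed inverse problem with a zero-residual optimum.

What the generator does **not** emulate: read sampling and taxonomic
mis-assignment, compositional count noise, metabolite detection limits and
batch effects, diet correlation structure across individuals, or any
mismatch between the capability database and the true metabolism. Passing
recovery tests therefore demonstrates the correctness and well-posedness
of the machinery under the model's own assumptions, not performance on
real cohorts.

## Identifiability of the byproduct fraction, and a known bias

The level count is sharply identified by calibration in every experiment.
The byproduct fraction f is only weakly identified: refitting the intake
at a wrong f absorbs much of the discrepancy, leaving mean-r margins of
order 1e-3 between neighbouring grid cells on noiseless cohorts. A margin
analysis across network families showed sparser networks (mean degree 2)
give the largest margins — hence the generator's default degree — but no
family makes f strongly identified.

Moreover, when *both* observation channels are noisy, argmax-r selection
is biased toward smaller f: lowering f steepens the level-decay gradient
of the predicted log-metabolome, and exaggerating the dominant gradient
raises the Pearson correlation against a noisy target even though the
profile is wrong. At 0.1 dex noise on both channels this bias is about
one 0.1-wide grid cell and the exact-cell recovery fraction drops to
roughly one half (log-accuracy selection is less affected). With either
channel noiseless, the truth cell is recovered. The calibration recovery
experiment reports exact-cell fractions for both selectors along with the
level-count recovery fraction; the numbers should be read with this bias
in mind. It is a property of correlation-based calibration itself, and is
consistent with the bootstrap spread of roughly ±0.05 in f that this kind
of calibration shows on real cohorts.

## Problem sizes and tolerances

Validation experiments (see `scripts/acceptance.py`) use: 200 random
instances for mass conservation (1e-9 relative); 50 sink-free instances
for the recursion-vs-operator oracle (1e-10); 20 noiseless samples of 40
species × 19 intakes for intake recovery (1e-3 componentwise, median
correlation ≥ 0.99); 10 replicate cohorts × 2 truth cells of 20 samples at
0.1 dex noise for calibration recovery on a 5 × 4 grid; 50 capability
shuffles against a 12-sample cohort for null degradation; 100 random
cohorts for the D_β ≥ 1 bound; a 105-point (r, n) grid against direct
numerical integration of the Student-t density for the adjusted P (1e-10).
These sizes run in minutes on one CPU.

## Known limitations

- Single global f and equal secretion split are simplifications; per-edge
  kinetic variants exist as robustness knobs, not fitted quantities
  (fitting them would add thousands of parameters).
- The trophic level count is a hard cutoff, not a residence-time model.
- The calibration f-bias above; prefer log-accuracy (or both selectors
  agreeing) when calibrating on noisy data.
- Genus handling assumes the first name token is the genus unless a genus
  map is supplied.
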