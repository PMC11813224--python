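# Methods

## Model

### Pathway topology

γ-secretase cleaves the C99 substrate endoproteolytically (ε cleavage) and
then trims the resulting long Aβ peptide carboxy-terminally in two parallel
product lines:

| branch | species chain | released coproducts |
|---|---|---|
| Aβ40 | C99 → Aβ49 → Aβ46 → Aβ43 → Aβ40 | AICD 50–99, ITL, VIV, IAT |
| Aβ42 | C99 → Aβ48 → Aβ45 → Aβ42 → Aβ38 | AICD 49–99, VIT, TVI, VVIA |

The topology is data, not code: `src/abtrim/data/pathway.yaml` declares the
branches, species and coproduct sequences, and `PathwayGraph` validates it
(acyclic linear chains, one endoproteolytic coproduct per branch, unique
species/coproduct names). All mass-balance code is written against the
graph, so an alternative trimming scheme is a YAML edit, not a code change.

### Mass balance

Each cleavage event releases exactly one soluble coproduct, so the measured
coproduct concentration counts the events of that step. For a chain
x₁ → x₂ → … → xₙ with coproducts c₁ … cₙ (c₁ endoproteolytic), the pool of
intermediate xᵢ remaining at assay end is

    [xᵢ] = [cᵢ] − [cᵢ₊₁]        (terminal: [xₙ] = [cₙ])

and the forward map is the suffix sum [cᵢ] = Σ_{j≥i} [xⱼ]. The forward map
is unitriangular on each branch and therefore exactly invertible; the
round trip is algebraically lossless apart from float rounding.

The percent cleavage efficiency of trimming step xᵢ → xᵢ₊₁ is
100·[cᵢ₊₁]/[cᵢ]. Endoproteolytic steps have no upstream coproduct and no
efficiency.

**Impossible values are evidence, not errors.** A negative pool means the
consuming coproduct was measured above the producing one; an efficiency
above 100% is the same inconsistency in ratio form. Both are returned
unclipped and flagged (`NEGATIVE_POOL`, `EFFICIENCY_GT_100`) so the
inconsistency stays visible in downstream tables. In the packaged mutant
data the S170F Aβ48→Aβ45 efficiency is 230% — a physically impossible
number that the analysis must surface, not silence.

### Censoring and ND

Cells below the lowest calibration standard are represented as
`Censored(limit)` (AICD assays: 62.5 nM), and undeterminable cells as the
`ND` sentinel — distinct from 0 and from NaN. Any pool whose defining
coproducts include a censored value becomes ND with a `BELOW_LOD` flag;
a pool whose precursor information is absent becomes ND with
`PRECURSOR_ND`. ND propagates by exclusion: ratios involving ND are ND,
and statistics drop ND observations while reporting how many were
excluded. Censoring one coproduct never perturbs pools it does not define
(a tested invariant).

### Linear-range kinetics

The simulator models the assay in its initial linear range at saturating
substrate: total turnovers N = k_cat·[E]·t (nM), split by the
endoproteolytic branch probability p₄₉, then thinned down each chain by
per-step continuation probabilities qᵢ. Expected coproduct i on a branch
is N·p_branch·Π_{j<i} qⱼ. Because each intermediate is committed once
(no re-binding of released peptides at saturating substrate), the step
efficiency of noiseless simulated data equals qᵢ exactly — the recovery
identity the tests verify to 1e-12.

Occupancy of stalled enzyme–intermediate complexes is computed from
optional per-step (k_cleave, k_release) rate pairs: a visited state's
weight is its visit probability times the mean residence time
1/(k_cleave + k_release), normalized over all visited states. The state
carries the step's *precursor* species (slowing Aβ48→Aβ45 piles up
E·Aβ48). Steps with zero total rate are an error only if actually visited.

### Isotope channels and calibration

Peptide elemental compositions and monoisotopic masses come from
pyteomics; the heavy (uniform ¹³C/¹⁵N) − light mass shift is
nC·1.0033548378 + nN·0.9970349 Da. `assign_channel` picks the nearest
theoretical mass within a tolerance (default 0.02 Da) and refuses ties.
Standard curves are ordinary least squares on internal-standard response
ratios (scipy `linregress`), with optional forced origin and log–log
fitting; inversion censors below the lowest standard rather than
extrapolating.

## Parameters (units and defaults)

| parameter | default | unit | rationale |
|---|---|---|---|
| `kcat` | 2.0 | hr⁻¹ | wild-type enzyme turnover in the detergent assay |
| `enzyme_conc` | 30 | nM | assay enzyme concentration |
| `time` | 16 | hr | assay duration (within the linear range) |
| `branch_p49` | 0.5 | — | near-even ε-cleavage split for wild type |
| `noise_cv` | 0.1 | — | typical replicate CV of the MS quantification |
| `n_replicates` | 4 | — | replicate count of the study design |
| `detection_floor` | None | nM | set to 62.5 to emulate the AICD lowest standard |
| mass tolerance | 0.02 | Da | channel assignment window |

Defaults mirror the study conditions the generator emulates; they were set
from those conditions up front, not adjusted against test outcomes.

## What the generator emulates (and what it does not)

Emulated: turnover-proportional coproduct totals, branch split, per-step
processivity, multiplicative replicate noise, detection-limit censoring,
and per-variant stall phenotypes (`datasets.scenarios`: `wt`,
`endo_deficient`, `f386s_like`, `palp_like` — scenario parameters are
qualitative caricatures of phenotype classes, not fitted per-variant
constants). Not emulated: time-dependent substrate depletion, product
re-binding/inhibition, ionization or digestion biases, carryover, or
between-day batch effects.

## Numerical choices

- **Noise.** Default `lognormal` with mean-one correction
  (σ² = ln(1+CV²), μ = −σ²/2) so the expectation is unbiased at any CV;
  `gaussian` and an exact `stochastic` mode (Poisson turnover count with
  binomial thinning down the chain) are available. All randomness flows
  through one `numpy.random.default_rng(seed)`; reruns with a seed are
  byte-identical.
- **Efficiency aggregation.** Default `per_replicate` (compute the
  efficiency in each replicate, then summarize) because ratios of means
  and means of ratios differ under noise; `pooled` (ratio of replicate
  means) is exposed as an option.
- **Calibration.** Linear OLS by default; log–log as an option for
  wide-dynamic-range curves. Forcing the origin is off by default (a
  nonzero intercept is itself diagnostic).
- **Statistics.** Unpaired two-tailed Student t-test (pooled variance) by
  default, matching small-n equal-design comparisons; Welch by option.
  Stars at p < 0.05/0.01/0.001. No multiple-testing correction is applied
  by default — the tables report raw p-values and leave family-wise
  decisions to the analyst.
- **kcat recovery** regresses total AICD (both branches) on time and
  divides the slope by [E]; it requires ≥2 distinct time points.
- **Formatting.** Concentrations serialize at 10 significant digits;
  `ND` ↔ `NA` and `Censored(L)` ↔ `CENSOREDL` round-trip through the CSV
  dialect.

## Limitations

- The mass balance assumes every cleavage releases exactly one detected
  coproduct and that coproducts are stable over the assay; degradation of
  a coproduct biases the corresponding pool downward.
- Linear-range kinetics ignore substrate depletion; at long times or low
  substrate the N = k_cat·[E]·t approximation overestimates turnovers.
- Occupancy fractions describe relative dwell among stalled complexes,
  not absolute enzyme engagement.
- Censored values contribute no information beyond their bound; no
  maximum-likelihood imputation below the limit is attempted.
- The t-tests assume approximate normality of replicate values; with
  n = 4 this is an assumption, not a verified property.
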