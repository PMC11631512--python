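# Methods

## Model structure and assumptions

The system couples 18 state variables — endothelial cells (EN), VEGF (V),
oxygen (Ox), four T-cell pools (TN, Th, Tc, Tr), dendritic cells (DN, D),
macrophages (MN, M), cancer (C), necrotic cells (N), adipocytes (A) and four
cytokines (H/HMGB1, IL-12, IL-10, IL-6) — through mass-action kinetics. All
variables are dimensionless: observations are divided by each variable's
maximum across all mice and stages, so data lie in [0, 1]; time stays in
days (week 6 of tumour progression is t = 0, sampling is biweekly, so the
four observation times are 0/14/28/42 days; simulations are typically run to
day 150).

Key structural choices:

- **Naive/activated bookkeeping.** Differentiation terms drain the naive
  pool and appear verbatim as sources of the activated pools, so the
  TN→(Th, Tc, Tr), DN→D and MN→M fluxes balance term by term. This is an
  invariant of the implementation and is property-tested.
- **Logistic growth** for EN (catalysed by VEGF), C (accelerated by IL-6 and
  adipocytes) and A, with carrying capacities EN0, C0, A0 treated as
  estimated parameters on the same [0, 2] box as the rates. The
  implementation guards the zero-capacity limit: a compartment with zero
  capacity cannot grow (the printed form divides by the capacity).
- **Hypoxia** acts through two decreasing Hill switches sharing the exponent
  `m`: `f1` at the normoxia→mild-hypoxia threshold drives HIF-type
  production terms (VEGF, IL-6, IL-10, dendritic maturation, Treg
  differentiation, extra T-cell cytotoxicity), `f2` at the mild→severe
  threshold drives hypoxic death. Macrophages are exempt from hypoxic death
  (they adapt to hypoxic niches); the activated dendritic pool reuses the
  naive pool's hypoxic death rate — one shared parameter, as in the source
  equations.
- **Oxygen** is sourced proportionally to EN (vessels) and consumed by six
  cell groups at rates `delta_1..delta_6`; its equation is integrated on the
  same day time scale as everything else (no separate fast time variable is
  defined anywhere, so the τ in the oxygen equation is read as t).
- **Necrosis** receives the fraction `alpha_NC` of all cancer death fluxes
  and clears at `delta_N`.

The registry holds every distinct rate symbol exactly once: 85 rates plus 3
capacities (88 estimated parameters), with the hypoxia-shape block
(`ox_crit1`, `ox_crit2`, `m`) as 3 extended parameters used by the
sensitivity analysis (91 columns). A mechanical enumeration of the equations
gives these counts; they are asserted in the test suite.

### Hypoxia defaults

`ox_crit1 = 0.2`, `ox_crit2 = 0.02`, `m = 5`. The thresholds are 1% and
0.1% O2 converted through the aqueous ppm scale (1% O2 ≈ 10 000 ppm ≈
0.625 mol/l with the atomic 16 g/mol convention) and divided by the week-6
maximum 3.125 mol/l. The exponent is a moderate-sharpness default; both the
thresholds and `m` are configurable and are included in the sensitivity
parameter axis.

### Numerics

LSODA with `rtol 1e-8`, `atol 1e-10` by default (cytokine decay is fast
relative to cell dynamics, so a stiff-capable method is required); the loss
uses relaxed `rtol 1e-6` for speed inside population search. Negative
excursions are clipped to zero only when smaller in magnitude than the
absolute tolerance, so genuine solver trouble remains visible. Integration
failure inside the loss returns a large finite penalty (1e6) so the GA can
continue; elsewhere it raises an `IntegrationError` carrying the failure
time.

## Data preparation

Tumour volumes follow the caliper convention `V = L*W^2/2`; with `L ≈ W`
the equivalent diameter is `(2V)^(1/3)`. The stage volumes 200/400/700/1400
mm³ (hyperplasia, adenoma/MIN, early and late carcinoma) give diameters
7.36/9.28/11.18/14.09 mm. A dissociation protocol recovers 4.5±0.9e7 cancer
cells and 2.2±0.6e6 TAMs per gram, where 1 g corresponds to two 10-mm
tumours; half the per-gram yield scaled by `d/10` gives per-stage estimates.

Reproducing the printed reference numbers fixes the rounding conventions
uniquely: diameters are **truncated** to two decimals (7.368→7.36,
11.186→11.18 — rounding would give 7.37/11.19), stage counts truncated to
three significant figures (2.25e7·0.736 = 1.656e7 → 1.65e7), and standard
deviations truncated on the mean's last-digit grid (0.2784e6 → 0.27e6).
Per-mouse anchors take mean + k·SD with k = −1, 0, +1 for mice 1–3.

Immune fractions (summing to 1 within the immune panel) become absolute
counts by anchoring on the TAM total (TAM = MN + M). Necrotic cells are set
to half the cancer count and excluded from the volume budget, since the
reported volumes exclude necrotic regions. Adipocyte and endothelial counts
solve the volume-budget equation: the residual volume after immune and
cancer cells is distributed over the non-immune types proportionally to
their panel fractions and single-cell caliper volumes (`L^3/2` at the
midpoint of each published size range; stromal/fibroblast populations are
folded into adipocytes at 20 µm). Oxygen ppm values are read as mg/l and
divided by 16 g/mol — the convention that reproduces the reference oxygen
table; a flag provides the physically correct 32 g/mol for molecular O2.

The bundled dataset ships the derived per-mouse count and cytokine tables
for three MMTV-PyMT mice. The per-mouse anchor rule reproduces the bundled
cancer counts exactly at 10 of the 12 mouse–stage pairs; at week 10 the
entries of mice 2 and 3 are interchanged relative to the rule, and the TAM
columns follow the (−1, 0, +1) ordering only at week 6. The tests assert the
consistent pairs and document the exceptions.

## Estimation

The loss is the unweighted sum of squared differences over mice, variables
and time points — justified because max-scaling puts every variable on the
same [0, 1] scale; a per-entry weight matrix is accepted for robustness
studies. Initial conditions are the observed week-6 states (a deliberate
choice, not estimated; estimating them is possible by extending the free
set). Each mouse is normally fitted independently.

GA defaults: population 200, up to 500 generations, 5% elitism, crossover
fraction 0.8, Gaussian mutation with σ starting at 10% of the box width and
shrinking geometrically 10-fold over the run, stall limit 50 generations at
function tolerance 1e-8, bounds [0, 2]. Selection uses rank-based
expectation scaling (expectation ∝ 1/√rank) and stochastic-uniform
line-walk sampling. The hybrid step polishes the GA best with bounded
L-BFGS-B on numerical gradients and never returns a point worse than its
start. Everything is reproducible from a single seed.

## Identifiability

Practical identifiability uses profile likelihoods on (optionally
5%-perturbed) synthetic data: each parameter is scanned over
`[0, 2*estimate]` (21 points by default), the remaining parameters
re-optimised at every grid point, warm-started outward from the estimate so
both branches stay in the right basin. The threshold is
`L(theta_hat) + chi2_alpha(1)` with α = 0.95 (Δ = 3.84) for pointwise
intervals. A profile crossing the threshold on both sides is *identifiable*;
failing on at least one side, *practically non-identifiable*; varying by
less than `0.1·Δ` overall, *flat* (suggesting local structural problems).

Two caveats are intentional. First, the χ² threshold applies to the raw
sum-of-squares, so its absolute scale is only calibrated when residuals are
noise-scaled; on noiseless synthetic data profiles rarely cross it and the
classifier will honestly report non-identifiability at that data scale.
Second, structural identifiability is outside this package's scope: the
observability/Lie-derivative analysis is an external symbolic computation
whose published conclusion (all parameters structurally identifiable when
every variable is observed) we record here without recomputing. Published
per-mouse counts of practically non-identifiable and flat parameters depend
on the optimiser, scan grids and noise draws and are treated as qualitative
expectations, not reproduction targets.

## Sensitivity analysis

The global analysis linearises the parameters→trajectory map: central
finite differences (relative step 1e-4, floor 1e-6, one halving retry on
solver failure) of every output on a fine grid (151 daily points on
[0, 150] by default) are stacked output-major into `M` with one column per
parameter (91 columns: 88 estimated + 3 hypoxia-shape). A thin SVD
`M = U Σ V^T` gives principal components `U_i`, the singular spectrum, and
principal sensitivity values `S_ij = σ_i V_ji`, with the linearisation
`δX = Σ_ij S_ij δk_j U_i + o(‖δk‖)` (the standard first-order form; a
variant with an extra σ factor sometimes seen in print is not a consistent
linearisation). The "scaled" mode multiplies column j by k_j, measuring
response to relative parameter changes; it is the default for heatmaps and
rankings. The spectrum cutoff (default 20% of σ₁) selects how many PCs to
inspect; heatmap entries keep |σ_i U_i| loadings above 20% of the global
maximum. For scalar outputs (cancer, total immune cells = TN+Th+Tc+Tr+DN+D+
MN+M, total cells) one singular value dominates, so the signed first-PC
sensitivities coincide with classical sensitivity; the sign convention
orients the first PC to have positive time-average so a positive value means
"increasing this parameter raises the output overall". Perturbation
experiments re-simulate at fractional offsets of one parameter (clipped with
a warning at the [0, 2] box) and report cancer/total-immune series with
their pointwise envelope.

## Synthetic data generator

The generator emulates the *shape* of the study's inputs, not its biology:
ground-truth parameter sets are uniform draws from the [0, 2] box (optional
sparsity mask for well-conditioned subsystems), accepted only if the model
integrates over [0, 150] (resampling up to a cap); observations sample the
biweekly grid and apply independent multiplicative noise, uniform ±5% by
default (lognormal optional), clipped at zero. The max-rescaling step is off
by default so a noiseless dataset has exactly zero loss at the truth —
simulated states are already non-dimensional. Default initial state: the
mean-anchored mouse's (mouse 2) week-6 scaled observations. Fraction/volume
tables are generated by inverting the count arithmetic, so the
data-preparation stage round-trips them exactly.

What passing synthetic tests does **not** show: real deconvolved fractions
carry estimation error and panel incompleteness, real cytokine expression is
not on the model's scale by construction, and real dynamics need the full
86-plus-parameter fit; the generator's closure properties validate the
pipeline's arithmetic and the estimator's behaviour, not the biology of any
particular mouse.

The recovery benchmark (`tmekin.synth.recovery_experiment`) fixes a sparse,
structurally identifiable truth — adipocyte logistic (`lambda_A = 0.15`,
`A0 = 0.8`) feeding IL-6 (`lambda_IL6A = 0.5`, `delta_IL6 = 0.4`) and a
cancer logistic (`lambda_C = 0.25`, `C0 = 0.9`) feeding HMGB1
(`lambda_HC = 0.6`, `delta_H = 0.3`) — and fits those 8 parameters with a
compact GA (population 40, 60 generations) plus refinement. Problem sizes
throughout the suite (population sizes, grid lengths, seed counts) are
chosen as the smallest that exercise each contract convincingly.

## Known limitations

- No spatial transport, chemotaxis, macrophage M1/M2 polarisation or
  glycolytic (Warburg) metabolic switching — deliberate scope limits of the
  lumped ODE description.
- The full 88-parameter fit to the bundled data is compute-heavy and its
  optimum is not unique at four time points per mouse (see the
  identifiability section); the package exposes it but the test suite
  exercises sparse subsystems.
- Deconvolution itself (fractions from expression data) is out of scope:
  fractions are consumed, never computed.
- The ppm→molar oxygen conversion follows the atomic-mass convention of the
  source tables by default; switch `molar_mass=32` for physical units.
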