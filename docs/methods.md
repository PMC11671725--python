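# Methods

## Model

Emitted soil N₂O is treated as a four-member isotope mixture over the
sources bD (bacterial denitrification), fD (fungal denitrification), Ni
(nitrification) and nD (nitrifier denitrification), observed in three
dimensions: site preference δ¹⁵N^SP, δ¹⁸O (referenced to soil water), and
the source partitioning coefficient SPC measured independently by the ¹⁵N
gas-flux method. SPC behaves as a third "isotopic" dimension whose source
values are 1 for the two denitrifying pathways and 0 otherwise, with no
fractionation.

Reduction of N₂O to N₂ follows the closed-system (Rayleigh)
approximation δ_r = δ₀ + ε·ln r with net reduction effects ε_SP and ε_O
and r the unreduced N₂O fraction. Two classical scenarios are supported:
RM (reduction then mixing — only the bacterial end member is shifted, by
ε·ln r, before mixing) and MR (mixing then reduction — the mixture is
shifted, equivalently the shift moves to the measurement side of the
linear system). The shipped source library carries the literature
signatures (bD −1.90±2.8 / 19.20±1.65‰, fD 33.50±3.18 / 47.20±3.28‰, Ni
35.00±1.68 / 23.50±3‰, nD −5.9±3.88 / 16.8±1.25‰; ε_SP −5±1.35‰, ε_O
−15±5‰), with SDs under the convention that a published range spans
mean ± 2 SD (`sd_from_range`).

## Linear-system Monte Carlo

Each draw samples 14 parameters independently from normal distributions:
the 8 source signatures, the 2 reduction effects, the 2 sample deltas, and
SPC and R_N₂O. SPC and R_N₂O draws are truncated-normal on (0, 1]
(rejected-and-redrawn), so the number of solved systems equals `n_draws`;
high-variance product ratios would otherwise yield unphysical values. The
4×4 system is solved exactly (vectorized batch solve); a draw is accepted
iff all four fractions lie in [−10⁻⁹, 1+10⁻⁹] (the tolerance absorbs
floating-point dust at the simplex boundary). Summaries are the mean ± SD
over accepted draws. The microscopic r in the logarithm is the drawn
R_N₂O — the standard linearization for bacteria-dominated soils. An
optional fixed-point mode instead iterates r ← f_bD·N₂O/(f_bD·N₂O + N₂)
with damping (factor ½, tolerance 10⁻⁶ on r, non-converged draws
rejected and counted); it quantifies the cost of that linearization.
A single seeded generator drives everything; the draw order (source
library block, sample deltas, SPC, R) is fixed, so runs are
bit-reproducible per seed.

`r_consistency_check` recomputes r from the ensemble mean f_bD and the
measured fluxes (RM: f̄_bD·N₂O/(f̄_bD·N₂O + N₂); MR: N₂O/(N₂O + N₂)) to
test the R_N₂O ≈ r assumption after the fact. With the packaged study
fluxes (N₂O 2.31, N₂ 3.26 µgN kg⁻¹ h⁻¹) and f̄_bD = 0.876 these
computations give 38.3% (RM) and 41.5% (MR).

## Bayesian sampler

Unknowns: the fraction simplex, r ∈ (0, 1], and the ten library
parameters (treated as chain state with their literature normals as
priors — the posterior thus integrates source uncertainty exactly rather
than conditioning on point values). Priors on the mixing state are
uniform: symmetric Dirichlet(1) on the simplex, uniform on r; the package
takes no stance on the "true" prior beyond these neutral choices.

The kernel alternates two move types per iteration:

1. **Library refresh** — blockwise independence proposals per source
   (its SP and δ¹⁸O jointly; the two ε jointly) drawn from the literature
   normals; because proposal = prior, the acceptance ratio is the
   likelihood ratio alone.
2. **Mixing move** — an additive Gaussian step in the simplex log-ratio
   coordinates (the softmax Jacobian, Σ log fᵢ, joins the uniform prior)
   and a reflected Gaussian step on r. Step SDs default to 0.05 and
   0.015, scaled by a symmetric 1/4/16 kick mixture (probabilities
   0.6/0.3/0.1) so the walk both resolves the sharp SPC ridge and
   occasionally crosses it; on study-like inputs this lands in the
   targeted 20–40% acceptance band.

Defaults: 200,000 iterations, 50% burn-in, no thinning. The likelihood is
Gaussian in the three observed dimensions; a zero measurement SD is
rejected as degenerate (in particular the SPC dimension uses the
measured across-replicate SD, ~0.0067, never a point value). The chain
starts at the deterministic mean-parameter solve when feasible (else the
barycenter). Acceptance below 0.1% raises a non-convergence warning.
Pearson correlations of the kept chain are reported with NaN for
numerically constant variables. Note that *correlations* converge much
more slowly than means: with the default chain length the f_bD–f_nD
correlation of a study-condition run still varies by ~±0.15 between
seeds, while fraction means are stable to a point or two.

## ¹⁵N gas-flux stage

The two-pool binomial model underlies everything: a gas drawing fraction
d from a labeled pool at atom fraction a_p (and 1−d from background at
a_b) has heavy-isotopologue excess mole fractions

    x_single = d[2a_p(1−a_p) − 2a_b(1−a_b)],   x_double = d[a_p² − a_b²].

The inversion is closed-form: the excess ratio q = x_single/x_double gives
the quadratic (2+q)a_p² − 2a_p + [2a_b(1−a_b) − q·a_b²] = 0, whose root in
(a_b, 1) is a_p; d follows from the double-heavy equation. Excesses below
3× the IRMS precisions (R29 1.5×10⁻⁶, R30 9.3×10⁻⁶, R45 3.1×10⁻⁵, R46
8.2×10⁻⁵) are flagged below detection; a gas is excluded only when *all*
its heavy excesses are below threshold, because at realistic enrichments
the single-heavy excess carries most of the signal (the double-heavy N₂
excess sits near its detection limit even when the data are clearly
usable).

Per replicate, the time-0 sample defines the background; the latest
above-detection sample is inverted against it. N₂O excesses are expressed
per mole of *emitted* N₂O (ambient N₂O subtracted at the isotopologue
level), so the recovered d is directly the SPC; N₂ excesses are expressed
against the (effectively constant) ambient N₂ reservoir, so d·[N₂]
converts to the denitrified N₂ flux. Concentration changes convert to
µgN kg⁻¹ h⁻¹ by the ideal gas law at the incubation temperature.
Headspace sampling (30 mL replaced by lab air from a ~333 mL headspace)
multiplies accumulated excesses by φ = (V−v)/V per event; the pipeline
divides by the cumulative factor. SPC and R_N₂O are computed per
replicate and then averaged (never as ratios of mean fluxes), with
across-replicate SDs (ddof = 1).

## Synthetic-data generator

`GroundTruth` defaults encode the study conditions this package targets: a
flooded agricultural soil strongly favoring denitrification — partition
(0.876, 0.0949, 0.0145, 0.0146) (so SPC = f_bD+f_fD = 0.9709), r = 0.4157,
N₂O flux 2.31 and denitrified N₂ flux 3.26 µgN kg⁻¹ h⁻¹, pool enrichments
51.14 / 47.08 atom%, jar geometry 450 mL / 150 g soil / 60 mL solution,
sampling at 0/3/6/24 h, and the stated 1σ instrument precisions (GC 6 ppb;
IRMS ratios above; δ precisions 0.1/0.1/0.5‰). r is carried independently
of the fluxes, mirroring the experimental practice of substituting the
measured R_N₂O for it; the generator does not force the two to agree.

Noise is Gaussian, independent across instruments and time points, with
no drift model, and δ noise applies to the final emitted-N₂O deltas
rather than raw detector signals. Emission rates are constant in time and
the partition is static. Consequently the simulator reproduces instrument
error propagation faithfully but contains no biological replicate
variability, nonlinear emission dynamics, dissolved-gas storage or O₂
microsite structure — passing recovery tests demonstrates correctness of
the inference chain under the stated measurement model, not robustness to
those real-world effects. One deliberate consequence: per-replicate
N₂-side estimates (a_p of N₂, denitrified N₂) are noise-limited because
the ³⁰N₂ excess is comparable to its IRMS precision at these conditions,
so their across-replicate scatter exceeds the study's published SDs,
which fold in replicate-consistent raw data.

## Numerical choices

- Condition numbers above 10¹² (e.g. duplicated source signatures) raise
  a degenerate-system error; batch solves mark singular draws rejected.
- Delta algebra identities are enforced to 10⁻⁹ ‰; the two-pool inversion
  round-trips to 10⁻¹²; product-ratio preconditions use 10⁻⁹ tolerances.
- Input CSVs are parsed with round-trip float precision and written at 17
  significant digits, so write→read is bit-exact.
- Percent vs fraction ambiguity in measurement files is resolved by an
  explicit `unit` column; internal canonical unit is fraction (deltas ‰).

## Known limitations

- The study-reproduction checks run against a forward-generated stand-in
  for the emitted-N₂O measurement (the measured values live in an external
  data deposit); they are self-consistency tests at the study conditions,
  not a re-derivation of the published table from raw data.
- Acceptance-conditioning in the constrained Monte Carlo biases ensemble
  means slightly toward the simplex interior when the truth sits at the
  boundary (~2–3 points on f_bD at study conditions).
- Only one fractionating process (N₂O reduction) and exactly four sources
  are modeled; no mixed RM/MR interpolation; no ¹⁷O anomaly handling
  beyond an optional constant mass-45 correction; no dissolved-gas or
  diffusion corrections for flooded incubations.
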