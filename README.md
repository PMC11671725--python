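# n2opart

Partitioning soil N₂O emissions among four microbial sources — bacterial
denitrification (bD), fungal denitrification (fD), nitrification (Ni) and
nitrifier denitrification (nD) — by fusing natural-abundance N₂O
isotopocule measurements with ¹⁵N gas-flux (¹⁵NGF) constraints from a
parallel tracer incubation.

## The problem and the model

Natural-abundance N₂O isotopocule data alone (site preference
δ¹⁵N^SP = δ¹⁵Nᵅ − δ¹⁵Nᵝ, and δ¹⁸O) cannot separate four sources: two
isotopic dimensions plus normalization give only three equations for four
unknown fractions, and partial reduction of N₂O to N₂ shifts the residual
gas along a Rayleigh line δ_r = δ₀ + ε·ln r (ε < 0, r the unreduced N₂O
fraction), entangling mixing with fractionation.

A parallel ¹⁵NO₃⁻-labeled incubation closes the system. From the headspace
²⁹/³⁰N₂ and ⁴⁵/⁴⁶N₂O isotopologue excesses, a two-pool binomial model
yields the ¹⁵N atom fraction a_p of the denitrifying pool and the fraction
d of each gas derived from it, hence the denitrified N₂O and N₂ fluxes,
the source partitioning coefficient SPC = N₂O_denitrified / N₂O_emitted
= f_bD + f_fD, and the macroscopic product ratio
R_N₂O = N₂O_den / (N₂O_den + N₂_den). The augmented system (here the
reduction-then-mixing scenario "RM", where only bacterial N₂O is reduced
before mixing) is

    f_bD(δ¹⁸O_bD + ε_O ln r) + f_fD δ¹⁸O_fD + f_Ni δ¹⁸O_Ni + f_nD δ¹⁸O_nD = δ¹⁸O_sample
    f_bD(δ¹⁵N^SP_bD + ε_SP ln r) + …                                     = δ¹⁵N^SP_sample
    f_bD + f_fD                                                           = SPC
    f_bD + f_fD + f_Ni + f_nD                                             = 1

with r ≈ R_N₂O (valid when bacteria dominate denitrification). In the
mixing-then-reduction scenario ("MR") the ε·ln r shift moves to the
right-hand side of the two isotopic rows. Two estimators solve it:

- **`MonteCarloPartitioner`** — draws all 14 parameters (source signatures,
  reduction effects, sample deltas, SPC, R_N₂O) from their normal
  distributions, solves each 4×4 system exactly, and keeps draws whose four
  fractions all land in [0, 1].
- **`BayesianPartitioner`** — treats the four fractions *and* r as unknowns
  (so no denitrified-N₂ measurement is needed), with SPC as a third mixing
  dimension whose source values are (1, 1, 0, 0) and which undergoes no
  fractionation. Metropolis–Hastings on the simplex × (0, 1], with the
  source signatures kept in the chain state under their literature priors.

Both follow the scikit-learn estimator idiom (`fit`, `get_params`,
fitted attributes with trailing underscores).

## Worked example

Simulate a study-condition dataset (4 replicate 450 mL jars, 150 g soil,
sampling at 0/3/6/24 h, ~50 atom% labeled nitrate pool), then partition:

```
$ n2opart simulate --seed 1 --out sim/
wrote sources.csv, measurement.csv, headspace.csv to sim

$ n2opart partition ls --scenario RM --draws 100000 --seed 1 \
    --measurement sim/measurement.csv --out ls.json
variable   mean %     sd %
f_bD         84.7      6.6
f_fD         12.3      6.6
f_Ni          1.5      0.9
f_nD          1.6      1.0
accepted 2890/100000 draws
```

Reading: bacterial denitrification carries ~85% of the N₂O emission,
fungal denitrification ~12%, the two nitrification pathways ~1.5% each;
the accepted fractions sum to 1 and f_bD + f_fD reproduces the measured
SPC (~97%) by construction. Only ~3% of draws satisfy all positivity
constraints — the method operates at the edge of the feasible simplex,
exactly the regime reported for strongly denitrifying soils. The
`gasflux` subcommand reduces the raw headspace table instead, and
`partition bayes` runs the MCMC sampler (adding a posterior for r and the
5×5 correlation matrix).

The same pipeline is available as a library:

```python
from n2opart import GroundTruth, forward_measurement, MonteCarloPartitioner

est = MonteCarloPartitioner(scenario="RM", n_draws=100_000, random_state=1)
est.fit(forward_measurement(GroundTruth()))
print(est.summary_)     # mean/sd per source fraction
```

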