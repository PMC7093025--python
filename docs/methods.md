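# Methods

This note documents the model, its numerical choices, the synthetic-data
generator, and the calibration procedure as implemented in `phytoalloc`,
including the design decisions that were genuinely open.

## Model structure and assumptions

The cell is described by carbon-normalized quotas (mol per mol cellular C)
of measurable macromolecular pools: three protein classes (photosynthetic,
biosynthetic, essential/other), chlorophyll, RNA, DNA, thylakoid
phospholipid, an essential carbohydrate+lipid pool, and three storage
pools (carbohydrate/lipid C storage, cyanophycin N storage, polyphosphate
P storage). Elemental budgets close exactly: carbon quotas sum to 1, and
N:C and P:C are the sums of the nitrogen and phosphorus pools weighted by
each molecule's fixed C:N:P.

Four relations connect pools to rates:

* per-chlorophyll photosynthesis saturates with light,
  v_I = v_I_max (1 − exp(−A_I I));
* the light-harvesting apparatus has fixed composition, so photosynthetic
  protein and thylakoid phospholipid are proportional to chlorophyll;
* biosynthetic protein is proportional to growth rate;
* RNA phosphorus is affine in protein × growth rate (the linear
  RNA:protein vs growth-rate relation).

With the steady-state carbon balance (photosynthesis = growth + synthesis
respiration + maintenance), chlorophyll is linear in growth rate at fixed
light; N:C and P:C follow as quadratics in μ whose curvature comes solely
from RNA; and setting carbon storage to zero yields the quadratic whose
positive root is the light-dependent growth ceiling μ_max(I). Closed
forms and the pool-by-pool assembly are implemented as two independent
code paths and cross-checked to 1e-12 in the tests.

Deliberately out of scope: photo-inhibition, temperature dependence,
nutrient-transporter allocation, P-lipid substitution, trace metals, and
any time-dependent (dynamic) acclimation; the chemostat layer is
steady-state algebra only.

## Stoichiometric constants

Nucleic-acid composition is derived from the four nucleoside-monophosphate
residues (base + pentose carry all C and N; the backbone phosphate carries
one P and no C/N), GC-weighted with equal G/C and equal A/U(T) fractions.
At the default GC fraction 0.563 this gives RNA C:N:P = 9.5:3.78:1 and
DNA 9.72:3.78:1 (RNA carbon per P is exactly 9.5 at any GC because the
A+U and G+C pairs carry equal carbon). Cyanophycin (equimolar Asp-Arg
polymer) has C:N = 2; polyphosphate carries no carbon. Protein N:C
(1/3.82), chlorophyll a N:C (4/55), and phospholipid C:P (40) are taken
as fixed constants; the phospholipid value is deliberately not re-derived
from a molecular structure because atom-count conventions for the acyl
chains are ambiguous. All constants can be overridden from a flat
JSON/YAML mapping (`--ratios`) for other organisms.

## Respiratory cost of synthesis, E

E (mol C respired per mol C synthesized) defaults to 14/15 ≈ 0.933,
derived by electron-equivalent bookkeeping for biomass C5H7O2N1P1/30
built from nitrate at energy-transfer efficiency 0.6: the biomass carries
5.6 e-eq per mol C (4 per C at mean oxidation state 0, plus 8 per N for
nitrate reduction, over 5 C), the carbohydrate donor carries 4 e-eq per C,
and at efficiency ε each e-eq transferred costs (1−ε)/ε e-eq respired.
`scripts/derive_respiratory_cost.py` reproduces the arithmetic. Growth on
ammonium would lower E (no nitrate-reduction term); E is an ordinary
config parameter, not a fitted one.

## Chemostat layer

At steady state μ = D, and the limiting nutrient is assumed drawn far
below its feed concentration, so biomass is feed concentration over the
non-storage quota of the limiting element. The limiting element is the
one supporting the smaller biomass — equivalently, feed N:P below the
required (non-storage) N:P means N limitation; an exact tie is classified
as N-limited by a fixed convention. Luxury storage of the non-limiting
element accrues to the lesser of availability and an empirical cap; the
caps are deliberately asymmetric (total P per C is capped, while only the
*storage* component of N is capped), reflecting that total P appears
roughly constant under N limitation whereas N storage appears roughly
constant under P limitation. Negative computed storage beyond a 1e-12
float tolerance raises a typed consistency error rather than silently
re-classifying the limitation.

Dilution above μ_max(I) raises a washout error (not NaN). Independently,
a steady state *below* μ_max can still be infeasible under P limitation
when cyanophycin carbon exhausts the carbon budget; the generator omits
both kinds of rows, as real chemostat datasets only contain points where
a steady culture existed.

## Numerical choices

* The growth-ceiling quadratic is solved in the cancellation-free form
  2c/(−b − √(b² − 4ac)); with a > 0 and c < 0 there is exactly one
  positive root, and the degenerate a = 0 (no RNA term) reduces to the
  linear root automatically.
* Infeasibility (no positive root; negative carbon storage beyond 1e-9)
  raises typed errors in the library API; inside the fitting loop each
  infeasible observation instead contributes a finite penalty of 1e6 to
  the error, keeping the error surface finite and monotonically
  improvable so chains can leave bad regions.
* Carbon closure assigns all unallocated carbon to C storage, making the
  pool sum exactly 1 by construction; tests verify 1e-12.

## Synthetic-data generator

The generator emulates a classic chemostat stoichiometry study: six
acclimation light levels (12–144 μmol photons m⁻² s⁻¹), dilution rates
0.05–1.0 d⁻¹ in steps of 0.05 at each light, one N-limited feed recipe
(0.8 mol N m⁻³, 0.05 mol P m⁻³; feed N:P = 16, below the required ratio)
and one P-limited recipe (0.8, 0.01; feed N:P = 80), observing Chl:C,
N:C, P:C and culture biomass per surviving condition plus μ_max per
light. Noise is multiplicative Gaussian (default 5 % relative s.d.,
truncated at zero since all observables are positive); the per-dataset
error scale σ_k is the noise s.d. times the mean noiseless value, floored
at 1 % so noise-free designs still define a finite error function.
Datasets group rows by (variable, limitation, light), mirroring how such
data are published panel by panel.

The packaged default organism is synthetic — order-of-magnitude plausible
for a freshwater cyanobacterium (μ_max ≈ 1 d⁻¹ at saturating light,
Chl:C a few percent, N:C 0.05–0.2, P:C 0.002–0.01), with the phosphorus
parameters placed in the regime where RNA dominates the cellular P budget
so that N:P declines with growth rate under P limitation. It is not a fit
to any published experiment. What passing tests show is therefore
internal consistency and recoverability under this idealized design; real
datasets add non-Gaussian scatter, light-dependent photophysiology
(acclimation of v_I_max and A_I, which the model deliberately holds
fixed), and species-specific composition that the generator does not
emulate.

## Calibration

The error function is Σ_k (1/n_k) Σ_i (data − model)² / (2σ_k²): squared
residuals scaled per dataset by 2σ_k², normalized by dataset size so
panels with many points do not dominate. A proposal is accepted when a
uniform random number is below exp(−(E_new − E_current)); the chain is
used as a stochastic optimizer (best state over the chain), not for
posterior inference.

Proposals are multiplicative, uniform in [0.8, 1.2]. By default each step
perturbs *one* uniformly chosen parameter of the active block; perturbing
the whole block jointly is available as an option but mixes poorly near
the optimum (a joint move only remains in a tight basin when every factor
lands near 1 simultaneously), and short chains then stall at percent-level
bias. Out-of-bounds proposals (negative values; chlorophyll parameters
above 5× their initial values by default) are rejected and counted as
non-accepted steps. All randomness flows from a single seed; identical
seed, data, and config give a bitwise-identical chain.

The calibration is staged along the model's triangular structure:
(1) m, v_I_max, A_I against Chl:C vs μ, which nothing else influences;
(2) A_Pho, A_Bio, Q_C_Pro_Other, Q_N_Sto_max, Q_C_Other against N:C
(both limitations), biomass under N limitation, and μ_max vs I;
(3) A_RNA_P, A_Pho_P:Chl, Q_P_Other against P:C and biomass under P
limitation. Stages 2 and 3 are mutually coupled (stage 2's N:C and μ_max
depend on the phosphorus parameters through RNA carbon and thylakoid
lipid), so the 2–3 block is swept twice by default, each sweep spending
half of each stage's step budget; a single pass can leave stage 2 biased
when the initial phosphorus values are far off. Stage 1 is independent
and runs once.

Default desk-scale budgets: 2×10⁴ steps for a stage-1-only fit, and
(2×10⁴, 5×10⁴, 3×10⁴) — 10⁵ total — for a full staged fit, which takes
roughly ten seconds on one core against the default design (~500
observations) thanks to a fully vectorized forward evaluator. Recovery
experiments initialize at truth × uniform[0.5, 2] per free parameter;
under the default design this recovers the stage-1 block to better than
1 % from noise-free data and all 11 parameters to well within 25 %
(median over five seeds) from 5 %-noise data.

## Known limitations

* The MH optimizer has no convergence diagnostics beyond acceptance rate
  and error traces; it is not a posterior sampler.
* σ_k estimation from data without replicates falls back to a fraction
  (default 10 %) of each dataset's observed range — a heuristic.
* The storage caps are empirical constants; the model has no mechanism
  for storage dynamics.
* Limitation is binary (N or P); co-limitation is not represented, and
  residual nutrient concentrations are not tracked (feed ≫ residual is
  hard-coded).
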