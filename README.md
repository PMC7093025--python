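# phytoalloc

A coarse-grained, steady-state model of phytoplankton physiology that links
**macromolecular allocation** (protein, chlorophyll, RNA, DNA, lipids,
storage polymers) to **elemental stoichiometry** (Chl:C, N:C, P:C, N:P),
**growth rate**, and **resource supply** (light, nitrogen, phosphorus), with
a staged Metropolis–Hastings calibration of its free parameters against
chemostat observations.

It is aimed at phytoplankton physiologists and biogeochemical modellers who
want a mechanistic but algebraically solvable alternative to Droop-style
quota models: one that explains *why* Chl:C and N:C rise linearly with
growth rate while P:C rises quadratically, why N:P falls with growth rate
under P limitation, and how the light-dependent maximum growth rate μᵐᵃˣ(I)
emerges from a carbon-allocation trade-off.

## The model

Four empirically grounded relations close the cellular C, N, and P budgets
(all quotas Q are mol per mol cellular C; rates d⁻¹; light I in
μmol photons m⁻² s⁻¹):

1. **Photosynthesis saturates with light**:
   v_I = v_I^max (1 − e^(−A_I·I)), per mol chlorophyll C.
2. **The light-harvesting apparatus has fixed composition**: photosynthetic
   protein and thylakoid phospholipid scale with chlorophyll,
   Q_C^ProPho = A_Pho·Q_C^Chl and Q_P^Thy = A_Pho^P:Chl·Q_C^Chl.
3. **Biosynthetic protein scales with growth rate**: Q_C^ProBio = A_Bio·μ.
4. **RNA scales with protein × growth rate** (the growth-rate hypothesis):
   Q_P^RNA = A_RNA^P·μ·Q_C^Pro + Q_P^RNA,min.

The steady-state carbon balance forces the chlorophyll quota to be linear
in growth rate, Q_C^Chl = (1+E)/v_I · μ + m/v_I, where m is maintenance
respiration and E the respiratory cost per carbon synthesized. Summing
pools weighted by their elemental composition gives closed-form quadratics
for N:C and P:C in μ at fixed light; requiring the carbon budget to close
with zero storage gives a quadratic whose positive root is μᵐᵃˣ(I).

At the culture level, a chemostat at steady state fixes μ = D (the dilution
rate); the limiting element is the one whose feed-to-quota ratio supports
the smaller biomass, and the non-limiting element accumulates as luxury
storage (polyphosphate or cyanophycin) up to empirical caps.

Eleven free parameters are calibrated by a staged Metropolis–Hastings
chain with ±20 % multiplicative proposals: first the chlorophyll block
(m, v_I^max, A_I) against Chl:C vs μ; then the nitrogen/carbon block
against N:C, biomass, and μᵐᵃˣ vs I; then the phosphorus block against
P:C and biomass under P limitation.

## Worked example

```python
import phytoalloc as pa

params = pa.default_params()          # packaged synthetic organism
ratios = pa.default_ratios()          # Table of C:N:P conversion constants

print(pa.mu_max(62.0, params, ratios))            # 0.6066 d^-1

env = pa.Environment(i=62.0, n_in=0.8, p_in=0.01, d=0.4)
state, biomass = pa.solve_culture(env, params, ratios)
print(state.limitation)               # 'P'
print(round(state.q_c_chl, 4))        # 0.04     chlorophyll C per cell C
print(round(state.n_to_c, 4))         # 0.1555   mol N / mol C
print(round(state.p_to_c, 5))         # 0.00503  mol P / mol C
print(round(state.n_to_p, 2))         # 30.93
print(round(biomass, 3))              # 1.989    mol C m^-3 in the culture
```

At this light a dilution rate of 0.4 d⁻¹ is ~2/3 of the growth ceiling.
The feed N:P of 80 exceeds the cell's required N:P, so the culture is
P-limited; the cell stores surplus nitrogen as cyanophycin up to its cap
(`state.q_n_sto == 0.02`) and keeps ~15 % of its carbon as storage
(`state.q_c_csto`).

Calibration composes with scikit-learn:

```python
from phytoalloc import AllocationModel, DesignSpec, generate

obs = generate(params, DesignSpec(seed=1))     # synthetic chemostat table
model = AllocationModel(seed=1).fit(obs)
model.params_        # best ModelParams over the chain
model.best_error_    # total sigma-scaled squared error
```

The same operations are exposed on the command line:

```sh
phytoalloc tables                      # C:N:P of each macromolecular pool
phytoalloc generate --seed 1 --out obs.csv
phytoalloc simulate --out curves.csv   # Chl:C, N:C, P:C, N:P vs (mu, I)
phytoalloc fit --obs obs.csv --seed 1 --out-dir fit/
```

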