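"""Synthetic chemostat datasets from a known parameter set.

Emulates the classic continuous-culture design used to characterize
phytoplankton stoichiometry: several acclimation light levels, a grid of
dilution rates at each (the experimenter's control on growth rate), one
N-limited and one P-limited feed recipe, and multiplicative measurement
noise on every observable.  Dilution rates above the light-dependent
maximum growth rate wash the culture out and produce no observation, as do
steady states whose carbon budget cannot close; such grid points are
silently omitted, mirroring how chemostat datasets only contain points
where the limiting nutrient was fully consumed.

The packaged default parameter set is a synthetic, order-of-magnitude
plausible freshwater-cyanobacterium-like organism used as the fixture for
all tests; it is not a fit to any published experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chemostat import Environment, solve_culture
from .core import mu_max
from .errors import (
    ConfigError,
    ConsistencyError,
    InfeasibleAllocationError,
    WashoutError,
)
from .params import ModelParams
from .stoich import StoichRatios, default_ratios

#: Relative noise floor used when deriving sigma_k, so that noiseless
#: datasets still carry a finite, well-scaled error weight.
SIGMA_FLOOR = 0.01


def default_params() -> ModelParams:
    """Synthetic default organism (freshwater cyanobacterium-like traits).

    Chosen once as a plausible mid-range parameterization: maximum growth
    around 1 d^-1 at saturating light, Chl:C of a few percent, N:C around
    0.1-0.2 and P:C around 0.005-0.01 over the feasible growth range.
    """
    return ModelParams(
        m=0.15,            # d^-1 maintenance respiration
        v_i_max=50.0,      # mol C (mol Chl C)^-1 d^-1
        a_i=0.01,          # (umol photons m^-2 s^-1)^-1; half-saturation ~70
        a_pho=6.0,         # photosynthetic protein C : chlorophyll C
        a_bio=0.15,        # d; biosynthetic protein C per unit mu
        q_c_pro_other=0.15,
        a_rna_p=0.015,     # mol P (mol C)^-1 d; RNA dominates the P budget
        q_p_rna_min=2.0e-4,
        a_pho_p_chl=0.02,  # mol P (mol Chl C)^-1
        q_p_other=3.0e-4,
        q_c_dna=0.01,
        q_c_other=0.25,
        q_n_sto_max=0.02,
        q_p_max=0.015,
    )


@dataclass(frozen=True)
class DesignSpec:
    """A chemostat experiment design.

    Attributes
    ----------
    light_levels : tuple of float
        Acclimation light intensities (umol photons m^-2 s^-1).
    dilution_grid : tuple of float
        Dilution rates (d^-1) attempted at every light level; points above
        the feasible maximum are washed out and omitted.
    scenarios : tuple of (feed_n, feed_p)
        Feed recipes (mol m^-3); the defaults give one N-limited and one
        P-limited culture series.
    noise_sd : float or mapping
        Relative (multiplicative) Gaussian noise s.d. per variable; a
        scalar applies to all variables.
    replicates : int
        Independent noisy measurements per culture condition.
    seed : int
        Generator seed (full determinism contract).
    """

    light_levels: tuple = (12.0, 25.0, 42.0, 62.0, 96.0, 144.0)
    dilution_grid: tuple = tuple(round(0.05 * k, 2) for k in range(1, 21))
    scenarios: tuple = ((0.8, 0.05), (0.8, 0.01))
    noise_sd: object = 0.05
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if any(d <= 0 for d in self.dilution_grid):
            raise ConfigError("dilution_grid values must be positive")
        sds = self.noise_sd.values() if isinstance(self.noise_sd, dict) else [self.noise_sd]
        if any(s < 0 for s in sds):
            raise ConfigError("noise_sd must be nonnegative")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")

    def sd_for(self, variable: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd.get(variable, 0.0))
        return float(self.noise_sd)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["light_levels"] = list(self.light_levels)
        d["dilution_grid"] = list(self.dilution_grid)
        d["scenarios"] = [list(s) for s in self.scenarios]
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignSpec":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("light_levels", "dilution_grid"):
            if key in d:
                d[key] = tuple(d[key])
        if "scenarios" in d:
            d["scenarios"] = tuple(tuple(s) for s in d["scenarios"])
        return cls(**d)


def _noisy(truth: float, sd: float, rng: np.random.Generator) -> float:
    """Multiplicative Gaussian noise truncated at zero (observables are
    positive ratios)."""
    if sd == 0:
        return truth
    for _ in range(100):
        value = truth * (1.0 + sd * rng.standard_normal())
        if value > 0:
            return value
    raise ConsistencyError("noise truncation failed to produce a positive value")


def generate(true_params: ModelParams, design: DesignSpec,
             ratios: StoichRatios | None = None) -> pd.DataFrame:
    """Generate a full observation table from a known parameter set.

    One dataset (sharing a sigma_k) per (variable, limitation, light) for
    the stoichiometric observables and the biomass, plus a single
    light-dependent maximum-growth-rate dataset.  sigma_k is the noise s.d.
    times the mean noiseless value of the dataset, floored at 1% so
    noiseless designs still define a finite error function.

    Returns a tidy DataFrame with columns ``dataset_id, variable, light,
    mu, value, limitation, feed_n, feed_p, sigma``.
    """
    if ratios is None:
        ratios = default_ratios()
    rng = np.random.default_rng(design.seed)
    rows: list[dict] = []

    for feed_n, feed_p in design.scenarios:
        for light in design.light_levels:
            for d in design.dilution_grid:
                env = Environment(i=light, n_in=feed_n, p_in=feed_p, d=d)
                try:
                    state, biomass = solve_culture(env, true_params, ratios)
                except (WashoutError, InfeasibleAllocationError, ConsistencyError):
                    continue
                truths = {
                    "chl_to_c": state.q_c_chl,
                    "n_to_c": state.n_to_c,
                    "p_to_c": state.p_to_c,
                    "biomass": biomass,
                }
                for _ in range(design.replicates):
                    for variable, truth in truths.items():
                        rows.append({
                            "dataset_id": f"{variable}|{state.limitation}|I={light:g}",
                            "variable": variable,
                            "light": light,
                            "mu": d,
                            "truth": truth,
                            "value": _noisy(truth, design.sd_for(variable), rng),
                            "limitation": state.limitation,
                            "feed_n": feed_n,
                            "feed_p": feed_p,
                        })

    for light in design.light_levels:
        truth = mu_max(light, true_params, ratios)
        for _ in range(design.replicates):
            rows.append({
                "dataset_id": "mu_max",
                "variable": "mu_max",
                "light": light,
                "mu": np.nan,
                "truth": truth,
                "value": _noisy(truth, design.sd_for("mu_max"), rng),
                "limitation": "N",
                "feed_n": np.nan,
                "feed_p": np.nan,
            })

    df = pd.DataFrame.from_records(rows)
    if df.empty:
        raise ConfigError("design produced no observable rows (all washed out)")
    sigma = {}
    for k, g in df.groupby("dataset_id"):
        sd = max(design.sd_for(g["variable"].iloc[0]), SIGMA_FLOOR)
        sigma[k] = sd * float(np.mean(np.abs(g["truth"])))
    df["sigma"] = df["dataset_id"].map(sigma)
    return df.drop(columns="truth")


def generate_noiseless(true_params: ModelParams, design: DesignSpec,
                       ratios: StoichRatios | None = None) -> pd.DataFrame:
    """The same table with noise_sd forced to zero (exact model values)."""
    quiet = DesignSpec(**{**asdict(design), "noise_sd": 0.0})
    return generate(true_params, quiet, ratios)
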