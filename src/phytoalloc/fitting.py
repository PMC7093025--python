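"""Staged Metropolis-Hastings calibration of the 11 free parameters.

The error function is a per-dataset sum of squared residuals scaled by
2 sigma_k^2, normalized by the dataset size n_k and summed over datasets.
Proposals perturb every active parameter jointly by independent uniform
multiplicative factors in [1-s, 1+s] (s = 0.2 by default); out-of-bounds
proposals are rejected outright and counted as non-accepted steps.  A
proposal is accepted with probability min(1, exp(-(E_new - E_current))), so
the chain behaves as a stochastic optimizer that can climb out of local
minima.

The calibration is staged, exploiting the model's triangular structure:

1. the three chlorophyll parameters (m, v_i_max, a_i) against Chl:C vs mu,
   which no other parameter influences;
2. the nitrogen/carbon-budget parameters (a_pho, a_bio, q_c_pro_other,
   q_n_sto_max, q_c_other) against N:C under both limitations, biomass
   under N limitation, and mu_max vs light, holding stage-1 values fixed;
3. the phosphorus parameters (a_rna_p, a_pho_p_chl, q_p_other) against
   P:C and biomass under P limitation.

Forward evaluation of a proposal is fully vectorized over the observation
table (closed-form algebra only), which keeps a 10^5-step chain to tens of
seconds on one core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, PhytoAllocError
from .params import (
    CHLOROPHYLL_PARAMS,
    FREE_PARAMS,
    NITROGEN_PARAMS,
    PHOSPHORUS_PARAMS,
    ModelParams,
)
from .stoich import StoichRatios, default_ratios

VARIABLES = ("chl_to_c", "n_to_c", "p_to_c", "biomass", "mu_max")
_VAR_CODE = {v: c for c, v in enumerate(VARIABLES)}
#: Variables whose forward evaluation needs the feed concentrations.
_NEEDS_FEED = {"n_to_c", "p_to_c", "biomass"}

REQUIRED_COLUMNS = ("dataset_id", "variable", "light", "mu", "value", "limitation")

DEFAULT_PENALTY = 1.0e6

STAGE_PARAMS = {1: CHLOROPHYLL_PARAMS, 2: NITROGEN_PARAMS, 3: PHOSPHORUS_PARAMS}


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Check the observation-table schema; return a clean copy.

    Raises :class:`ConfigError` naming the offending columns/rows.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"observations missing required columns: {missing}")
    df = df.copy()
    bad_var = ~df["variable"].isin(VARIABLES)
    if bad_var.any():
        raise ConfigError(
            f"unknown variable values in rows {list(df.index[bad_var])}: "
            f"{sorted(df.loc[bad_var, 'variable'].unique())}"
        )
    bad_lim = ~df["limitation"].isin(("N", "P"))
    if bad_lim.any():
        raise ConfigError(f"limitation must be 'N' or 'P' in rows {list(df.index[bad_lim])}")
    needs = df["variable"].isin(_NEEDS_FEED)
    for col in ("feed_n", "feed_p"):
        if col not in df.columns:
            df[col] = np.nan
        bad = needs & ~np.isfinite(df[col].to_numpy(dtype=float))
        if bad.any():
            raise ConfigError(
                f"column {col} must be finite for variables {sorted(_NEEDS_FEED)}; "
                f"offending rows {list(df.index[bad])}"
            )
    if (df["light"].to_numpy(dtype=float) <= 0).any():
        raise ConfigError("light must be positive for all observations")
    mu = df["mu"].to_numpy(dtype=float)
    stoich_rows = df["variable"] != "mu_max"
    if (stoich_rows & ~(mu >= 0)).any():
        raise ConfigError("mu must be nonnegative for all non-mu_max observations")
    return df


def estimate_sigma(df: pd.DataFrame, frac: float = 0.1) -> pd.Series:
    """Per-dataset measurement-error scale sigma_k.

    Uses the pooled standard deviation of replicate observations (rows of a
    dataset sharing the same light and dilution rate) when replicates
    exist; otherwise falls back to ``frac`` times the dataset's observed
    value range (or |mean| for degenerate single-value datasets).
    """
    out = {}
    for k, g in df.groupby("dataset_id"):
        reps = g.groupby(["light", "mu"])["value"]
        sizes = reps.size()
        if (sizes > 1).any():
            # pooled SD over replicate groups
            ss = 0.0
            dof = 0
            for _, vals in reps:
                if len(vals) > 1:
                    ss += ((vals - vals.mean()) ** 2).sum()
                    dof += len(vals) - 1
            sigma = np.sqrt(ss / dof) if dof else 0.0
        else:
            sigma = 0.0
        if sigma == 0.0:
            rng_ = g["value"].max() - g["value"].min()
            scale = rng_ if rng_ > 0 else abs(g["value"].mean())
            sigma = frac * scale
        if sigma <= 0:
            raise ConfigError(f"cannot estimate a positive sigma for dataset {k!r}")
        out[k] = sigma
    return pd.Series(out, name="sigma")


class CompiledObservations:
    """Observation table pre-compiled to flat arrays for fast evaluation.

    Splitting the (cheap, parameter-independent) indexing work from the
    per-proposal model evaluation is what makes a long chain affordable.
    """

    def __init__(self, df: pd.DataFrame, sigma: pd.Series | None = None,
                 sigma_frac: float = 0.1):
        df = validate_observations(df)
        if sigma is None:
            if "sigma" in df.columns and np.isfinite(df["sigma"]).all():
                sigma = df.groupby("dataset_id")["sigma"].first()
            else:
                sigma = estimate_sigma(df, frac=sigma_frac)
        self.df = df
        self.n_rows = len(df)
        self.value = df["value"].to_numpy(dtype=float)
        self.mu = np.nan_to_num(df["mu"].to_numpy(dtype=float))
        self.var_code = df["variable"].map(_VAR_CODE).to_numpy(dtype=np.int64)
        self.feed_n = df["feed_n"].to_numpy(dtype=float)
        self.feed_p = df["feed_p"].to_numpy(dtype=float)
        light = df["light"].to_numpy(dtype=float)
        self.lights, self.light_idx = np.unique(light, return_inverse=True)
        datasets, self.dataset_idx = np.unique(
            df["dataset_id"].to_numpy(), return_inverse=True
        )
        self.datasets = list(datasets)
        missing = set(self.datasets) - set(sigma.index)
        if missing:
            raise ConfigError(f"sigma missing for datasets: {sorted(missing)}")
        self.sigma = sigma.loc[self.datasets].to_numpy(dtype=float)
        if not (self.sigma > 0).all():
            raise ConfigError("all sigma_k must be positive")
        self.n_k = np.bincount(self.dataset_idx, minlength=len(self.datasets)).astype(float)
        self._inv_2s2 = 1.0 / (2.0 * self.sigma**2)
        # mask reused every evaluation
        self._needs_state = np.isin(
            self.var_code,
            [_VAR_CODE["n_to_c"], _VAR_CODE["p_to_c"], _VAR_CODE["biomass"]],
        )

    def subset(self, mask: np.ndarray) -> "CompiledObservations":
        sigma = pd.Series(self.sigma, index=self.datasets)
        return CompiledObservations(self.df.loc[mask], sigma=sigma)

    # -- forward evaluation -------------------------------------------------

    def evaluate(self, params: ModelParams, ratios: StoichRatios):
        """Model values for every row, plus a per-row infeasibility flag.

        Returns ``(model, bad)``; ``model`` entries for bad rows are
        meaningless and must be masked by the caller.  Returns
        ``(None, None)`` if the parameter set is globally infeasible (no
        positive growth root at some light).
        """
        v_i = params.v_i_max * -np.expm1(-params.a_i * self.lights)
        a_chl_u = (1.0 + params.e) / v_i
        b_chl_u = params.m / v_i
        thyl = 1.0 + params.a_pho + ratios.y_plip_cp * params.a_pho_p_chl
        q_other_tot = params.q_c_pro_other + params.q_c_dna + params.q_c_other
        a_m = ratios.y_rna_cp * params.a_rna_p * (params.a_pho * a_chl_u + params.a_bio)
        b_m = (
            thyl * a_chl_u
            + params.a_bio
            + ratios.y_rna_cp * params.a_rna_p
            * (params.a_pho * b_chl_u + params.q_c_pro_other)
        )
        c_m = thyl * b_chl_u + q_other_tot + ratios.y_rna_cp * params.q_p_rna_min - 1.0
        if (c_m >= 0).any():
            return None, None
        mumax_u = 2.0 * c_m / (-b_m - np.sqrt(b_m * b_m - 4.0 * a_m * c_m))

        li = self.light_idx
        mu = self.mu
        a_chl = a_chl_u[li]
        b_chl = b_chl_u[li]
        mumax = mumax_u[li]

        q_chl = a_chl * mu + b_chl
        q_pro = params.a_pho * q_chl + params.a_bio * mu + params.q_c_pro_other
        q_p_rna = params.a_rna_p * mu * q_pro + params.q_p_rna_min
        q_n_nonsto = (
            ratios.y_chl_nc * q_chl
            + ratios.y_pro_nc * q_pro
            + ratios.y_rna_np * q_p_rna
            + ratios.y_dna_nc * params.q_c_dna
        )
        q_p_thy = params.a_pho_p_chl * q_chl
        q_p_nonsto = (
            q_p_rna
            + ratios.y_dna_pc * params.q_c_dna
            + q_p_thy
            + params.q_p_other
        )

        with np.errstate(divide="ignore", invalid="ignore"):
            cell_n = self.feed_n / q_n_nonsto
            cell_p = self.feed_p / q_p_nonsto
            n_limited = self.feed_n * q_p_nonsto <= self.feed_p * q_n_nonsto
            # luxury storage of the non-limiting element
            q_p_pot = self.feed_p / cell_n
            q_p_sto = np.where(
                n_limited, np.minimum(q_p_pot, params.q_p_max) - q_p_nonsto, 0.0
            )
            q_n_pot = self.feed_n / cell_p
            q_n_sto = np.where(
                n_limited, 0.0,
                np.minimum(q_n_pot, params.q_n_sto_max + q_n_nonsto) - q_n_nonsto,
            )
            csto = 1.0 - (
                q_chl
                + q_pro
                + ratios.y_rna_cp * q_p_rna
                + params.q_c_dna
                + ratios.y_plip_cp * q_p_thy
                + ratios.y_nsto_cn * q_n_sto
                + params.q_c_other
            )

        # Washout and carbon-deficit checks apply to rows that require a
        # consistent culture state; the Chl:C line itself is defined at any
        # growth rate, so stage-1 data are never penalized through mu_max,
        # which stage 1 does not constrain.
        bad = self._needs_state & (
            (mu > mumax * (1 + 1e-12))
            | (q_p_sto < 0)
            | (csto < -1e-9)
            | ~np.isfinite(csto)
        )

        model = np.empty(self.n_rows)
        vc = self.var_code
        model[vc == 0] = q_chl[vc == 0]
        m1 = vc == 1
        model[m1] = (q_n_nonsto + q_n_sto)[m1]
        m2 = vc == 2
        model[m2] = (q_p_nonsto + q_p_sto)[m2]
        m3 = vc == 3
        model[m3] = np.where(n_limited, cell_n, cell_p)[m3]
        m4 = vc == 4
        model[m4] = mumax[m4]
        return model, bad

    def error(self, params: ModelParams, ratios: StoichRatios,
              penalty: float = DEFAULT_PENALTY) -> float:
        """Total normalized error of a parameter set on these observations.

        Infeasible rows (washout, negative storage or carbon deficit) each
        contribute the penalty instead of a residual, so the chain sees a
        finite, monotone-improvable error everywhere.
        """
        model, bad = self.evaluate(params, ratios)
        if model is None:
            return penalty * self.n_rows
        good = ~bad
        res = np.where(good, self.value - model, 0.0)
        per_dataset = np.bincount(
            self.dataset_idx, weights=res * res, minlength=len(self.datasets)
        ) * self._inv_2s2
        total = float(np.sum(per_dataset / self.n_k))
        n_bad = int(np.count_nonzero(bad))
        return total + penalty * n_bad


# ---------------------------------------------------------------------------
# Spec-level error operations (simple, explicit forms)
# ---------------------------------------------------------------------------

def dataset_error(params: ModelParams, data_k: pd.DataFrame,
                  forward: Callable[[ModelParams, pd.DataFrame], np.ndarray],
                  sigma: float, penalty: float = DEFAULT_PENALTY) -> float:
    """Sum of squared residuals of one dataset scaled by 2 sigma^2.

    ``forward`` maps (params, dataset rows) to model values; forward-model
    failures yield the finite penalty so the chain can move on.
    """
    if not sigma > 0:
        raise ConfigError("sigma must be positive")
    try:
        model = np.asarray(forward(params, data_k), dtype=float)
    except PhytoAllocError:
        return penalty
    res = data_k["value"].to_numpy(dtype=float) - model
    return float(np.sum(res * res) / (2.0 * sigma * sigma))


def total_error(per_dataset_errors: Sequence[float], n_k: Sequence[int]) -> float:
    """Combine dataset errors, each normalized by its number of points."""
    errors = np.asarray(per_dataset_errors, dtype=float)
    counts = np.asarray(n_k, dtype=float)
    if (counts < 1).any():
        raise ConfigError("all n_k must be >= 1")
    return float(np.sum(errors / counts))


def forward_evaluate(params: ModelParams, df: pd.DataFrame,
                     ratios: StoichRatios | None = None) -> np.ndarray:
    """Model values for a tidy observation table (one value per row).

    Raises :class:`PhytoAllocError` if any row is infeasible at ``params``.
    """
    if ratios is None:
        ratios = default_ratios()
    df = df.copy()
    if "value" not in df.columns:
        df["value"] = 0.0
    if "dataset_id" not in df.columns:
        df["dataset_id"] = "all"
    compiled = CompiledObservations(df, sigma=pd.Series(
        1.0, index=df["dataset_id"].unique()))
    model, bad = compiled.evaluate(params, ratios)
    if model is None:
        raise PhytoAllocError("parameter set infeasible (no positive growth root)")
    if bad.any():
        raise PhytoAllocError(
            f"{int(bad.sum())} rows infeasible (washout or carbon deficit)"
        )
    return model


# ---------------------------------------------------------------------------
# Metropolis-Hastings machinery
# ---------------------------------------------------------------------------

def accept(error_new: float, error_current: float, random_uniform: float) -> bool:
    """The acceptance rule: u < min(1, exp(-(E_new - E_current)))."""
    if error_new <= error_current:
        return True
    return random_uniform < np.exp(error_current - error_new)


def mh_step(current: tuple[np.ndarray, float],
            error_fn: Callable[[np.ndarray], float],
            proposal_scale: float,
            bounds: tuple[np.ndarray, np.ndarray],
            rng: np.random.Generator,
            joint: bool = False) -> tuple[np.ndarray, float, bool]:
    """One Metropolis-Hastings step on a parameter vector.

    By default one uniformly chosen component is perturbed by a uniform
    multiplicative factor in [1-s, 1+s]; with ``joint=True`` every
    component receives an independent factor in one move.  Coordinate-wise
    updates mix far better near the optimum (a joint move only stays in a
    tight basin when all factors land near 1 simultaneously), which is
    what makes short chains reach percent-level recovery.  A proposal
    outside ``bounds`` is rejected without evaluating the model and counts
    as a non-accepted step.

    Returns ``(params, error, accepted)`` for the (possibly unchanged)
    current state.
    """
    x, e = current
    if joint:
        factors = rng.uniform(1.0 - proposal_scale, 1.0 + proposal_scale,
                              size=x.shape)
        proposal = x * factors
    else:
        j = int(rng.integers(x.size))
        proposal = x.copy()
        proposal[j] *= rng.uniform(1.0 - proposal_scale, 1.0 + proposal_scale)
    lower, upper = bounds
    if (proposal < lower).any() or (proposal > upper).any():
        return x, e, False
    e_new = error_fn(proposal)
    if accept(e_new, e, rng.uniform()):
        return proposal, e_new, True
    return x, e, False


@dataclass
class StageResult:
    """Chain diagnostics for one calibration stage."""

    stage: int
    param_names: tuple[str, ...]
    best: dict
    best_error: float
    error_trace: np.ndarray      # current-state error at every step
    accepted: list               # (step, param vector, error) at acceptances
    acceptance_rate: float


@dataclass
class FitResult:
    """Outcome of a staged calibration.

    ``chain`` flattens the accepted states of all stages, each as a
    (parameter dict, error) pair; ``best_params`` carries the best state of
    every stage merged into one full parameter set.
    """

    best_params: ModelParams
    best_error: float
    stages: list[StageResult]
    rng_seed: int

    @property
    def chain(self) -> list[tuple[dict, float]]:
        out = []
        for s in self.stages:
            for _, x, e in s.accepted:
                out.append((dict(zip(s.param_names, x)), e))
        return out

    @property
    def acceptance_rate(self) -> float:
        total = sum(len(s.error_trace) for s in self.stages)
        acc = sum(len(s.accepted) for s in self.stages)
        return acc / total if total else 0.0


@dataclass
class FitConfig:
    """Configuration of the staged calibration.

    ``steps`` gives the chain length per stage.  ``bound_factors`` maps
    parameter names to an upper bound expressed as a multiple of the
    initial value; by default only the chlorophyll parameters are capped
    (at 5x), parameters are otherwise only required to stay positive.
    """

    init_params: ModelParams
    steps: tuple[int, int, int] = (20000, 20000, 20000)
    proposal_scale: float = 0.2
    seed: int = 0
    bound_factors: dict = field(
        default_factory=lambda: {p: 5.0 for p in CHLOROPHYLL_PARAMS}
    )
    penalty: float = DEFAULT_PENALTY
    sigma_frac: float = 0.1
    stages: tuple[int, ...] = (1, 2, 3)
    #: Perturb all active parameters in one move instead of one randomly
    #: chosen coordinate per step.  Coordinate-wise updates (the default)
    #: localize far better in short chains; see :func:`mh_step`.
    joint_proposal: bool = False
    #: Number of sweeps over the coupled stages 2 and 3.  Stage 2's forward
    #: model depends on the phosphorus parameters (through RNA carbon and
    #: thylakoid lipid) and stage 3's on the nitrogen ones, so a single
    #: pass leaves stage 2 biased by the initial stage-3 values; a second
    #: sweep re-fits both blocks from the other's calibrated values.
    #: Stage 1 is strictly independent and always runs once.
    cycles: int = 2


def _stage_mask(df: pd.DataFrame, stage: int) -> np.ndarray:
    var = df["variable"]
    lim = df["limitation"]
    if stage == 1:
        return (var == "chl_to_c").to_numpy()
    if stage == 2:
        return (
            (var == "n_to_c")
            | ((var == "biomass") & (lim == "N"))
            | (var == "mu_max")
        ).to_numpy()
    if stage == 3:
        return ((var == "p_to_c") | (var == "biomass")) .to_numpy() & (lim == "P").to_numpy()
    raise ConfigError(f"unknown stage {stage}")


_STAGE_REQUIRED = {1: {"chl_to_c"}, 2: {"n_to_c", "mu_max"}, 3: {"p_to_c"}}


def run_chain(compiled: CompiledObservations, params: ModelParams,
              names: Sequence[str], steps: int, config: FitConfig,
              ratios: StoichRatios, rng: np.random.Generator) -> StageResult:
    """Run one MH chain over the named free parameters, others held fixed."""
    names = tuple(names)
    x0 = np.array([getattr(params, n) for n in names], dtype=float)
    lower = np.zeros_like(x0)
    upper = np.array(
        [config.bound_factors.get(n, np.inf) * x0[i] for i, n in enumerate(names)]
    )

    def error_fn(x: np.ndarray) -> float:
        return compiled.error(params.replace(**dict(zip(names, x))), ratios,
                              penalty=config.penalty)

    x, e = x0, error_fn(x0)
    best_x, best_e = x, e
    trace = np.empty(steps)
    accepted: list = []
    s = config.proposal_scale
    for step in range(steps):
        x, e, acc = mh_step((x, e), error_fn, s, (lower, upper), rng,
                            joint=config.joint_proposal)
        trace[step] = e
        if acc:
            accepted.append((step, x, e))
            if e < best_e:
                best_x, best_e = x, e
    stage_no = next((k for k, v in STAGE_PARAMS.items() if v == names), 0)
    return StageResult(
        stage=stage_no,
        param_names=names,
        best=dict(zip(names, best_x)),
        best_error=best_e,
        error_trace=trace,
        accepted=accepted,
        acceptance_rate=len(accepted) / steps if steps else 0.0,
    )


def staged_fit(data: pd.DataFrame, config: FitConfig,
               ratios: StoichRatios | None = None) -> FitResult:
    """Calibrate the free parameters stage by stage.

    Each stage runs an independent MH chain on its parameter block against
    its observation subset, starting from ``config.init_params`` with
    earlier stages' best values substituted in.  Stages 2 and 3 are swept
    ``config.cycles`` times (their forward models depend on each other's
    parameters), each sweep spending an equal share of the stage's step
    budget; stage 1 is independent of the rest and runs once.
    """
    if ratios is None:
        ratios = default_ratios()
    data = validate_observations(data)
    sigma = None
    if "sigma" in data.columns and np.isfinite(data["sigma"]).all():
        sigma = data.groupby("dataset_id")["sigma"].first()
    else:
        sigma = estimate_sigma(data, frac=config.sigma_frac)
    rng = np.random.default_rng(config.seed)
    params = config.init_params

    coupled = [s for s in config.stages if s > 1]
    schedule: list[tuple[int, int]] = []
    if 1 in config.stages:
        schedule.append((1, config.steps[0]))
    cycles = max(config.cycles, 1) if coupled else 0
    for _ in range(cycles):
        for stage in coupled:
            schedule.append((stage, config.steps[stage - 1] // cycles))

    compiled_cache: dict[int, CompiledObservations] = {}
    stage_results = []
    for stage, steps in schedule:
        if stage not in compiled_cache:
            mask = _stage_mask(data, stage)
            present = set(data.loc[mask, "variable"].unique())
            missing = _STAGE_REQUIRED[stage] - present
            if missing:
                raise ConfigError(
                    f"stage {stage} requires variables {sorted(missing)} "
                    "absent from data"
                )
            compiled_cache[stage] = CompiledObservations(data.loc[mask], sigma=sigma)
        result = run_chain(
            compiled_cache[stage], params, STAGE_PARAMS[stage], steps, config,
            ratios, rng,
        )
        params = params.replace(**result.best)
        stage_results.append(result)
    full = CompiledObservations(data, sigma=sigma)
    return FitResult(
        best_params=params,
        best_error=full.error(params, ratios, penalty=config.penalty),
        stages=stage_results,
        rng_seed=config.seed,
    )
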