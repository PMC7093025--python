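"""Culture-level steady-state layer.

A chemostat at steady state pins the population growth rate to the dilution
rate (mu = D) and, under the standard assumption that the limiting nutrient
is drawn down far below its feed concentration, the carbon biomass in the
culture is simply the feed concentration of the limiting element divided by
the cell's non-storage quota of that element.  The limiting element is the
one yielding the smaller biomass (equivalently: feed N:P below the required
non-storage N:P means N limitation).  The non-limiting element accumulates
as luxury storage, capped empirically: total P per C is capped at q_p_max,
while N *storage* is capped at q_n_sto_max.  Whatever carbon the functional
pools and N-storage polymer do not claim is carbon storage.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    CLOSURE_TOL,
    AllocationState,
    allocation_state,
    mu_max,
    n_to_c,
    p_to_c,
)
from .errors import (
    ConsistencyError,
    DegenerateFeedError,
    DomainError,
    InfeasibleAllocationError,
    WashoutError,
)
from .params import ModelParams
from .stoich import StoichRatios, default_ratios


@dataclass(frozen=True)
class Environment:
    """Chemostat forcing: light, feed concentrations, dilution rate.

    Attributes
    ----------
    i : float
        Light intensity (umol photons m^-2 s^-1).
    n_in : float
        Dissolved inorganic N in the feed (mol m^-3).
    p_in : float
        Dissolved inorganic P in the feed (mol m^-3).
    d : float
        Dilution rate (d^-1); equals the growth rate at steady state.
    """

    i: float
    n_in: float
    p_in: float
    d: float

    def __post_init__(self):
        for name in ("i", "n_in", "p_in", "d"):
            if getattr(self, name) < 0:
                raise DomainError(f"environment field {name} must be nonnegative")


def biomass_if_limited(element: str, env: Environment, q_nonsto: float) -> float:
    """Carbon biomass (mol C m^-3) if ``element`` were the limiting one.

    Feed concentration divided by the non-storage quota of the element,
    from the steady-state nutrient balance with uptake V = mu * Q_nonsto
    and the feed >> residual approximation.
    """
    if element not in ("N", "P"):
        raise DomainError(f"element must be 'N' or 'P', got {element!r}")
    if not q_nonsto > 0:
        raise DomainError("non-storage quota must be positive")
    feed = env.n_in if element == "N" else env.p_in
    return feed / q_nonsto


def determine_limitation(env: Environment, q_n_nonsto: float, q_p_nonsto: float) -> str:
    """Which element limits: 'N' or 'P'.

    N-limited iff feed N:P < required (non-storage) N:P; ties classify as
    N-limited by convention.  Equivalent to taking the element whose
    single-element biomass is smaller.
    """
    if not (q_n_nonsto > 0 and q_p_nonsto > 0):
        raise DomainError("non-storage quotas must be positive")
    if env.n_in == 0 and env.p_in == 0:
        raise DegenerateFeedError("both feed concentrations are zero")
    # Cross-multiplied form of n_in/p_in <= q_n/q_p, robust to p_in = 0.
    return "N" if env.n_in * q_p_nonsto <= env.p_in * q_n_nonsto else "P"


def apply_storage(
    env: Environment,
    state: AllocationState,
    params: ModelParams,
    ratios: StoichRatios,
) -> AllocationState:
    """Fill the luxury-storage pools of the non-limiting element.

    The non-limiting element is taken up to the lesser of its
    availability-implied potential quota (feed over the biomass set by the
    limiting element) and its empirical cap.  Under N limitation the cap is
    on *total* P per C (q_p_max); under P limitation it is on the N
    *storage* component (q_n_sto_max).  N storage carries cyanophycin
    carbon; P storage (polyphosphate) carries none.
    """
    q_n_nonsto = state.n_to_c - state.q_n_sto
    q_p_nonsto = state.p_to_c - state.q_p_sto
    if state.limitation == "N":
        biomass = biomass_if_limited("N", env, q_n_nonsto)
        q_p_pot = env.p_in / biomass
        q_p = min(q_p_pot, params.q_p_max)
        q_p_sto = q_p - q_p_nonsto
        if q_p_sto < -1e-12:
            raise ConsistencyError(
                "feed P cannot cover even the non-storage P quota under N "
                "limitation; the steady state does not exist"
            )
        state.q_p_sto = max(q_p_sto, 0.0)
        state.q_n_sto = 0.0
        state.q_c_nsto = 0.0
    else:
        biomass = biomass_if_limited("P", env, q_p_nonsto)
        q_n_pot = env.n_in / biomass
        q_n_max = params.q_n_sto_max + q_n_nonsto
        q_n = min(q_n_pot, q_n_max)
        q_n_sto = q_n - q_n_nonsto
        if q_n_sto < -1e-12:
            raise ConsistencyError(
                "feed N cannot cover even the non-storage N quota under P "
                "limitation; the steady state does not exist"
            )
        q_n_sto = max(q_n_sto, 0.0)
        state.q_n_sto = q_n_sto
        state.q_c_nsto = ratios.y_nsto_cn * q_n_sto
        state.q_p_sto = 0.0
    return state


def close_carbon(state: AllocationState) -> AllocationState:
    """Assign all unallocated carbon to carbon storage.

    After closure the carbon pools sum to exactly 1.  A deficit beyond the
    closure tolerance means the requested growth rate is infeasible for
    this composition (it exceeds the effective maximum).
    """
    other = state.carbon_sum() - state.q_c_csto
    csto = 1.0 - other
    if csto < -CLOSURE_TOL:
        raise InfeasibleAllocationError(
            "carbon pools exceed the cellular budget (negative C storage): "
            "growth rate above the feasible maximum",
            residual=csto,
        )
    state.q_c_csto = max(csto, 0.0)
    return state


def solve_culture(
    env: Environment,
    params: ModelParams,
    ratios: StoichRatios | None = None,
) -> tuple[AllocationState, float]:
    """Full steady-state solution of one chemostat condition.

    Pipeline: mu = D -> non-storage quotas -> limiting element -> luxury
    storage with caps -> carbon closure -> biomass.  Raises
    :class:`WashoutError` if D exceeds mu_max(I), and propagates
    infeasibility from the closure.

    Returns
    -------
    (state, biomass) : (AllocationState, float)
        The fully consistent allocation state and the culture carbon
        biomass (mol C m^-3).
    """
    if ratios is None:
        ratios = default_ratios()
    mx = mu_max(env.i, params, ratios)
    if env.d > mx * (1 + 1e-12):
        raise WashoutError(env.d, mx)
    mu = env.d
    q_n_nonsto = n_to_c(mu, env.i, params, ratios, check_feasible=False)
    q_p_nonsto = p_to_c(mu, env.i, params, ratios, check_feasible=False)
    limitation = determine_limitation(env, q_n_nonsto, q_p_nonsto)
    state = allocation_state(mu, env.i, params, ratios, limitation=limitation)
    state = apply_storage(env, state, params, ratios)
    state = close_carbon(state)
    limiting_q = q_n_nonsto if limitation == "N" else q_p_nonsto
    biomass = biomass_if_limited(limitation, env, limiting_q)
    return state, biomass


def evaluate_batch(df, params: ModelParams, ratios: StoichRatios | None = None):
    """Solve a table of chemostat conditions.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``i, d, n_in, p_in`` (one row per culture condition).

    Returns
    -------
    pandas.DataFrame
        Input columns plus ``status`` ('ok', 'washout' or 'infeasible'),
        ``limitation, chl_to_c, n_to_c, p_to_c, n_to_p, biomass, q_c_csto,
        q_n_sto, q_p_sto``.  Failed rows are flagged, not dropped.
    """
    import pandas as pd

    if ratios is None:
        ratios = default_ratios()
    records = []
    for row in df.itertuples(index=False):
        env = Environment(i=row.i, n_in=row.n_in, p_in=row.p_in, d=row.d)
        rec = {"i": row.i, "d": row.d, "n_in": row.n_in, "p_in": row.p_in}
        try:
            state, biomass = solve_culture(env, params, ratios)
        except WashoutError:
            rec["status"] = "washout"
        except (InfeasibleAllocationError, ConsistencyError):
            rec["status"] = "infeasible"
        else:
            rec.update(
                status="ok",
                limitation=state.limitation,
                chl_to_c=state.q_c_chl,
                n_to_c=state.n_to_c,
                p_to_c=state.p_to_c,
                n_to_p=state.n_to_p,
                biomass=biomass,
                q_c_csto=state.q_c_csto,
                q_n_sto=state.q_n_sto,
                q_p_sto=state.q_p_sto,
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)
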