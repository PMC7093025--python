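"""Cell-level forward model.

Closed-form steady-state relations between growth rate, light, and cellular
composition: the saturating photosynthesis law, the linear chlorophyll-to-
carbon relation, the proportional allocation rules for photosynthetic and
biosynthetic machinery, and the closed-form quadratics for the maximum
light-dependent growth rate, N:C and P:C.

Sketch of the model.  Per-chlorophyll photosynthesis saturates with light,
v_I = v_I_max (1 - exp(-A_I I)).  A steady-state carbon balance
(photosynthesis = growth + its respiratory overhead + maintenance) forces
the chlorophyll quota to be linear in growth rate,

    Q_C_Chl = A_Chl(I) mu + B_Chl(I),
    A_Chl = (1 + E)/v_I,   B_Chl = m/v_I.

Photosynthetic protein and thylakoid phospholipid scale with chlorophyll
(fixed composition of the light-harvesting apparatus), biosynthetic protein
scales with growth rate, and RNA phosphorus scales with protein times growth
rate (the RNA:protein vs growth-rate relation).  Summing pools weighted by
their elemental composition gives N:C and P:C as quadratics in mu at fixed
light; requiring all carbon to be allocated with zero storage gives a
quadratic whose positive root is the maximum growth rate mu_max(I).

All functions accept scalars or numpy arrays for ``mu`` and ``i`` (light).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import (
    DomainError,
    InfeasibleAllocationError,
    SingularLightError,
)
from .params import ModelParams
from .stoich import StoichRatios, default_ratios

#: Absolute tolerance on the carbon-closure residual before an allocation is
#: declared infeasible (negative carbon storage).
CLOSURE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Photosynthesis and the chlorophyll-to-carbon relation
# ---------------------------------------------------------------------------

def photosynthesis_rate(i, params: ModelParams):
    """Gross photosynthesis per chlorophyll C, v_I(I) (d^-1).

    Saturating in light: v_I = v_I_max (1 - exp(-A_I I)).  Strictly
    increasing, bounded by v_I_max.
    """
    i = np.asarray(i, dtype=float)
    if np.any(i < 0):
        raise DomainError("light intensity must be nonnegative")
    out = params.v_i_max * -np.expm1(-params.a_i * i)
    return out if out.ndim else float(out)


def chl_coefficients(i, params: ModelParams):
    """Slope and intercept (A_Chl, B_Chl) of the Chl:C vs growth-rate line."""
    v = np.asarray(photosynthesis_rate(i, params), dtype=float)
    if np.any(v <= 0):
        raise SingularLightError("Chl:C is undefined at zero light (v_I = 0)")
    a = (1.0 + params.e) / v
    b = params.m / v
    if a.ndim:
        return a, b
    return float(a), float(b)


def chl_to_c(mu, i, params: ModelParams):
    """Chlorophyll-carbon quota Q_C_Chl at (mu, I).

    Solves the steady state of the cellular carbon balance
    v_I Q_C_Chl - (1+E) mu - m = 0, i.e. Q_C_Chl = A_Chl mu + B_Chl.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise DomainError("growth rate must be nonnegative")
    a, b = chl_coefficients(i, params)
    out = a * mu + b
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# Allocation rules
# ---------------------------------------------------------------------------

class AllocationRules(NamedTuple):
    """Pools set by the proportional allocation rules (all mol:mol C)."""

    q_c_pro_pho: object  # photosynthetic protein C
    q_p_thy: object      # thylakoid phospholipid P
    q_c_pro_bio: object  # biosynthetic protein C
    q_p_rna: object      # RNA P
    q_c_plip_thy: object  # thylakoid phospholipid C (via Y_Plip C:P)
    q_c_rna: object      # RNA C (via Y_RNA C:P)


def allocation_rules(
    mu, q_c_chl, q_c_pro, params: ModelParams, ratios: StoichRatios
) -> AllocationRules:
    """Apply the proportionality rules at given mu, chlorophyll and protein.

    Photosynthetic protein and thylakoid phospholipid are proportional to
    chlorophyll; biosynthetic protein is proportional to growth rate; RNA
    phosphorus is affine in (protein C x growth rate).  Carbon equivalents
    of the P pools follow from the phospholipid and RNA C:P ratios.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0) or np.any(np.asarray(q_c_chl) < 0) or np.any(np.asarray(q_c_pro) < 0):
        raise DomainError("allocation_rules inputs must be nonnegative")
    q_c_pro_pho = params.a_pho * q_c_chl
    q_p_thy = params.a_pho_p_chl * q_c_chl
    q_c_pro_bio = params.a_bio * mu
    q_p_rna = params.a_rna_p * mu * q_c_pro + params.q_p_rna_min
    return AllocationRules(
        q_c_pro_pho=q_c_pro_pho,
        q_p_thy=q_p_thy,
        q_c_pro_bio=q_c_pro_bio,
        q_p_rna=q_p_rna,
        q_c_plip_thy=ratios.y_plip_cp * q_p_thy,
        q_c_rna=ratios.y_rna_cp * q_p_rna,
    )


def protein_quota(mu, i, params: ModelParams):
    """Total protein C quota: photosynthetic + biosynthetic + essential."""
    q_chl = chl_to_c(mu, i, params)
    return params.a_pho * q_chl + params.a_bio * np.asarray(mu, float) + params.q_c_pro_other


# ---------------------------------------------------------------------------
# Maximum growth rate at a given light
# ---------------------------------------------------------------------------

def mu_max_coefficients(i, params: ModelParams, ratios: StoichRatios):
    """Coefficients (a_M, b_M, c_M) of the carbon-closure quadratic in mu.

    Setting carbon storage (and N storage) to zero in the carbon budget and
    substituting the allocation rules yields a_M mu^2 + b_M mu + c_M = 0.
    """
    a_chl, b_chl = chl_coefficients(i, params)
    thyl = 1.0 + params.a_pho + ratios.y_plip_cp * params.a_pho_p_chl
    q_c_other_tot = params.q_c_pro_other + params.q_c_dna + params.q_c_other
    a_m = ratios.y_rna_cp * params.a_rna_p * (params.a_pho * a_chl + params.a_bio)
    b_m = (
        thyl * a_chl
        + params.a_bio
        + ratios.y_rna_cp * params.a_rna_p * (params.a_pho * b_chl + params.q_c_pro_other)
    )
    c_m = thyl * b_chl + q_c_other_tot + ratios.y_rna_cp * params.q_p_rna_min - 1.0
    return a_m, b_m, c_m


def mu_max(i, params: ModelParams, ratios: StoichRatios | None = None):
    """Maximum growth rate mu_max(I) (d^-1): the nutrient-replete ceiling.

    The positive root of the carbon-closure quadratic, evaluated in the
    cancellation-free form 2 c_M / (-b_M - sqrt(b_M^2 - 4 a_M c_M)).
    Requires c_M < 0 (fixed pools plus maintenance leave room to grow);
    otherwise the parameter set is infeasible at this light.
    """
    if ratios is None:
        ratios = default_ratios()
    a_m, b_m, c_m = mu_max_coefficients(i, params, ratios)
    a_m, b_m, c_m = np.broadcast_arrays(
        np.asarray(a_m, float), np.asarray(b_m, float), np.asarray(c_m, float)
    )
    if np.any(c_m >= 0):
        raise InfeasibleAllocationError(
            "no positive growth rate: fixed pools plus maintenance exceed the "
            "carbon budget at this light"
        )
    disc = b_m * b_m - 4.0 * a_m * c_m
    # a_m > 0 and c_m < 0 guarantee disc > b_m^2 >= 0 and exactly one
    # positive root.  The degenerate a_m = 0 (no RNA growth term) reduces to
    # the linear solution -c_m / b_m, which the stable form handles too.
    root = 2.0 * c_m / (-b_m - np.sqrt(disc))
    return root if root.ndim else float(root)


# ---------------------------------------------------------------------------
# Elemental ratios: closed forms and pool sums
# ---------------------------------------------------------------------------

def nc_coefficients(i, params: ModelParams, ratios: StoichRatios):
    """Coefficients (a_N, b_N, c_N) of N:C = a_N mu^2 + b_N mu + c_N.

    The intercept c_N excludes nitrogen storage; add Q_N_Sto separately.
    The quadratic term comes solely from RNA nitrogen, so it vanishes when
    a_rna_p = 0 and N:C is then exactly linear in mu.
    """
    a_chl, b_chl = chl_coefficients(i, params)
    growth_pro = params.a_bio + params.a_pho * a_chl
    base_pro = params.a_pho * b_chl + params.q_c_pro_other
    a_n = ratios.y_rna_np * params.a_rna_p * growth_pro
    b_n = (
        ratios.y_chl_nc * a_chl
        + ratios.y_pro_nc * growth_pro
        + ratios.y_rna_np * params.a_rna_p * base_pro
    )
    c_n = (
        ratios.y_chl_nc * b_chl
        + ratios.y_pro_nc * base_pro
        + ratios.y_rna_np * params.q_p_rna_min
        + ratios.y_dna_nc * params.q_c_dna
    )
    return a_n, b_n, c_n


def pc_coefficients(i, params: ModelParams, ratios: StoichRatios):
    """Coefficients (a_P, b_P, c_P) of P:C = a_P mu^2 + b_P mu + c_P.

    The intercept c_P excludes phosphorus storage; add Q_P_Sto separately.
    """
    a_chl, b_chl = chl_coefficients(i, params)
    growth_pro = params.a_bio + params.a_pho * a_chl
    base_pro = params.a_pho * b_chl + params.q_c_pro_other
    a_p = params.a_rna_p * growth_pro
    b_p = params.a_rna_p * base_pro + params.a_pho_p_chl * a_chl
    c_p = (
        params.q_p_rna_min
        + ratios.y_dna_pc * params.q_c_dna
        + params.a_pho_p_chl * b_chl
        + params.q_p_other
    )
    return a_p, b_p, c_p


def _check_feasible(mu, i, params, ratios, check):
    if check:
        mx = mu_max(i, params, ratios)
        if np.any(np.asarray(mu, float) > np.asarray(mx, float) * (1 + 1e-12)):
            raise InfeasibleAllocationError(
                "growth rate exceeds mu_max at this light"
            )


def n_to_c(mu, i, params: ModelParams, ratios: StoichRatios | None = None,
           q_n_sto=0.0, check_feasible: bool = True):
    """Cellular N:C at (mu, I), optionally including nitrogen storage."""
    if ratios is None:
        ratios = default_ratios()
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise DomainError("growth rate must be nonnegative")
    _check_feasible(mu, i, params, ratios, check_feasible)
    a_n, b_n, c_n = nc_coefficients(i, params, ratios)
    out = (a_n * mu + b_n) * mu + c_n + q_n_sto
    return out if np.ndim(out) else float(out)


def p_to_c(mu, i, params: ModelParams, ratios: StoichRatios | None = None,
           q_p_sto=0.0, check_feasible: bool = True):
    """Cellular P:C at (mu, I), optionally including phosphorus storage."""
    if ratios is None:
        ratios = default_ratios()
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise DomainError("growth rate must be nonnegative")
    _check_feasible(mu, i, params, ratios, check_feasible)
    a_p, b_p, c_p = pc_coefficients(i, params, ratios)
    out = (a_p * mu + b_p) * mu + c_p + q_p_sto
    return out if np.ndim(out) else float(out)


def n_to_p(mu, i, params: ModelParams, ratios: StoichRatios | None = None,
           q_n_sto=0.0, q_p_sto=0.0, check_feasible: bool = True):
    """Cellular N:P at (mu, I) as the ratio of N:C to P:C."""
    pc = np.asarray(p_to_c(mu, i, params, ratios, q_p_sto, check_feasible), float)
    if np.any(pc <= 0):
        raise DomainError("P:C must be positive to form N:P")
    out = np.asarray(n_to_c(mu, i, params, ratios, q_n_sto, check_feasible), float) / pc
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Full allocation state
# ---------------------------------------------------------------------------

@dataclass
class AllocationState:
    """All quota pools for one (mu, I, environment) steady-state solution.

    Carbon pools sum to exactly 1 after closure; the nitrogen and
    phosphorus pool sums are the cellular N:C and P:C.
    """

    mu: float
    i: float
    limitation: str = "N"
    # carbon pools (mol C / mol C)
    q_c_chl: float = 0.0
    q_c_pro_pho: float = 0.0
    q_c_pro_bio: float = 0.0
    q_c_pro_other: float = 0.0
    q_c_rna: float = 0.0
    q_c_dna: float = 0.0
    q_c_plip_thy: float = 0.0
    q_c_nsto: float = 0.0
    q_c_csto: float = 0.0
    q_c_other: float = 0.0
    # nitrogen pools (mol N / mol C)
    q_n_chl: float = 0.0
    q_n_pro: float = 0.0
    q_n_rna: float = 0.0
    q_n_dna: float = 0.0
    q_n_sto: float = 0.0
    # phosphorus pools (mol P / mol C)
    q_p_rna: float = 0.0
    q_p_dna: float = 0.0
    q_p_thy: float = 0.0
    q_p_sto: float = 0.0
    q_p_other: float = 0.0

    _CARBON_POOLS = (
        "q_c_chl", "q_c_pro_pho", "q_c_pro_bio", "q_c_pro_other", "q_c_rna",
        "q_c_dna", "q_c_plip_thy", "q_c_nsto", "q_c_csto", "q_c_other",
    )
    _NITROGEN_POOLS = ("q_n_chl", "q_n_pro", "q_n_rna", "q_n_dna", "q_n_sto")
    _PHOSPHORUS_POOLS = ("q_p_rna", "q_p_dna", "q_p_thy", "q_p_sto", "q_p_other")

    def carbon_pools(self) -> dict:
        return {k: getattr(self, k) for k in self._CARBON_POOLS}

    def carbon_sum(self) -> float:
        return sum(self.carbon_pools().values())

    @property
    def n_to_c(self) -> float:
        return sum(getattr(self, k) for k in self._NITROGEN_POOLS)

    @property
    def p_to_c(self) -> float:
        return sum(getattr(self, k) for k in self._PHOSPHORUS_POOLS)

    @property
    def n_to_p(self) -> float:
        return self.n_to_c / self.p_to_c

    @property
    def q_c_pro(self) -> float:
        return self.q_c_pro_pho + self.q_c_pro_bio + self.q_c_pro_other

    def functional_classes(self) -> dict:
        """Carbon regrouped into photosynthetic / biosynthetic / storage / other."""
        return {
            "photo": self.q_c_chl + self.q_c_pro_pho + self.q_c_plip_thy,
            "bio": self.q_c_pro_bio + self.q_c_rna,
            "store": self.q_c_nsto + self.q_c_csto,
            "other": self.q_c_pro_other + self.q_c_dna + self.q_c_other,
        }


def allocation_state(
    mu: float, i: float, params: ModelParams,
    ratios: StoichRatios | None = None,
    q_n_sto: float = 0.0, q_p_sto: float = 0.0,
    limitation: str = "N",
) -> AllocationState:
    """Assemble the full pool-by-pool state at (mu, I), without C closure.

    Builds every carbon, nitrogen, and phosphorus pool from the allocation
    rules and the stoichiometric conversions; the carbon-storage pool is
    left at zero for :func:`phytoalloc.chemostat.close_carbon` to fill.
    """
    if ratios is None:
        ratios = default_ratios()
    mu = float(mu)
    q_chl = chl_to_c(mu, i, params)
    q_pro = protein_quota(mu, i, params)
    rules = allocation_rules(mu, q_chl, q_pro, params, ratios)
    return AllocationState(
        mu=mu,
        i=float(i),
        limitation=limitation,
        q_c_chl=q_chl,
        q_c_pro_pho=rules.q_c_pro_pho,
        q_c_pro_bio=rules.q_c_pro_bio,
        q_c_pro_other=params.q_c_pro_other,
        q_c_rna=rules.q_c_rna,
        q_c_dna=params.q_c_dna,
        q_c_plip_thy=rules.q_c_plip_thy,
        q_c_nsto=ratios.y_nsto_cn * q_n_sto,
        q_c_other=params.q_c_other,
        q_n_chl=ratios.y_chl_nc * q_chl,
        q_n_pro=ratios.y_pro_nc * q_pro,
        q_n_rna=ratios.y_rna_np * rules.q_p_rna,
        q_n_dna=ratios.y_dna_nc * params.q_c_dna,
        q_n_sto=q_n_sto,
        q_p_rna=rules.q_p_rna,
        q_p_dna=ratios.y_dna_pc * params.q_c_dna,
        q_p_thy=rules.q_p_thy,
        q_p_sto=q_p_sto,
        q_p_other=params.q_p_other,
    )
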