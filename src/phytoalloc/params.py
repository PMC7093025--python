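"""Forward-model parameterization.

Units convention (package-wide): rates in d^-1, light in umol photons
m^-2 s^-1, all quotas in mol per mol cellular C.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace, fields
from pathlib import Path

from .errors import DomainError

#: Default respiratory cost of synthesis E (mol C respired per mol C
#: synthesized), from electron-equivalent bookkeeping for biomass
#: C5H7O2N1P1/30 built from nitrate at energy transfer efficiency 0.6:
#: 28 e-eq per 5 mol biomass C, carbohydrate donor at 4 e-eq per C, so
#: E = (28/5) * (1 - 0.6)/0.6 / 4 = 14/15.  Re-derivable with
#: scripts/derive_respiratory_cost.py.
DEFAULT_E = 14.0 / 15.0

#: The three parameters controlling the chlorophyll-vs-growth relation;
#: they are fitted first and independently of everything else.
CHLOROPHYLL_PARAMS = ("m", "v_i_max", "a_i")

#: Parameters fitted in the second stage (nitrogen / carbon budget).
NITROGEN_PARAMS = ("a_pho", "a_bio", "q_c_pro_other", "q_n_sto_max", "q_c_other")

#: Parameters fitted in the third stage (phosphorus budget).
PHOSPHORUS_PARAMS = ("a_rna_p", "a_pho_p_chl", "q_p_other")

#: All 11 free parameters, in stage order.
FREE_PARAMS = CHLOROPHYLL_PARAMS + NITROGEN_PARAMS + PHOSPHORUS_PARAMS


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the allocation model.

    The 11 free (fitted) parameters plus the fixed pools and the
    respiratory cost ``e``.

    Attributes
    ----------
    m : float
        Maintenance respiration rate (d^-1).
    v_i_max : float
        Maximum photosynthesis rate per chlorophyll C
        (mol C (mol Chl C)^-1 d^-1).
    a_i : float
        Light-saturation coefficient ((umol photons m^-2 s^-1)^-1).
    e : float
        Respiratory cost per mol C synthesized (dimensionless).
    a_pho : float
        Photosynthetic-protein C per chlorophyll C (dimensionless).
    a_bio : float
        Biosynthetic-protein C per unit growth rate (d).
    q_c_pro_other : float
        Constant ("essential") protein pool (mol C (mol C)^-1).
    a_rna_p : float
        RNA P per (protein C x growth rate) (mol P (mol C)^-1 d).
    q_p_rna_min : float
        Minimum RNA P at zero growth (mol P (mol C)^-1).
    a_pho_p_chl : float
        Thylakoid phospholipid P per chlorophyll C (mol P (mol Chl C)^-1).
    q_p_other : float
        Constant other-P pool (mol P (mol C)^-1).
    q_c_dna : float
        DNA carbon pool (mol C (mol C)^-1).
    q_c_other : float
        Constant essential carbohydrate+lipid carbon pool (mol C (mol C)^-1).
    q_n_sto_max : float
        Maximum nitrogen *storage* per C (mol N (mol C)^-1).
    q_p_max : float
        Maximum *total* phosphorus per C (mol P (mol C)^-1).
    """

    m: float
    v_i_max: float
    a_i: float
    e: float = DEFAULT_E
    a_pho: float = 0.0
    a_bio: float = 0.0
    q_c_pro_other: float = 0.0
    a_rna_p: float = 0.0
    q_p_rna_min: float = 0.0
    a_pho_p_chl: float = 0.0
    q_p_other: float = 0.0
    q_c_dna: float = 0.0
    q_c_other: float = 0.0
    q_n_sto_max: float = 0.0
    q_p_max: float = float("inf")

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise DomainError(f"parameter {f.name} must be nonnegative, got {v}")
        if not self.v_i_max > 0:
            raise DomainError("v_i_max must be > 0")
        if not self.a_i > 0:
            raise DomainError("a_i must be > 0")
        if self.q_c_pro_other + self.q_c_dna + self.q_c_other >= 1.0:
            raise DomainError(
                "fixed carbon pools (q_c_pro_other + q_c_dna + q_c_other) "
                "must sum to < 1"
            )

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["q_p_max"] == float("inf"):
            d["q_p_max"] = None  # JSON has no inf
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        if d.get("q_p_max") is None:
            d["q_p_max"] = float("inf")
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DomainError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def free_values(self) -> dict:
        return {k: getattr(self, k) for k in FREE_PARAMS}

    def save(self, path: str | Path) -> None:
        """Serialize as flat JSON keyed by field name."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))
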