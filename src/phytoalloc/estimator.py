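"""scikit-learn-style front end to the allocation model.

:class:`AllocationModel` wraps the staged Metropolis-Hastings calibration
behind the familiar ``fit`` / ``predict`` contract so the model composes
with scikit-learn pipelines and model selection.  ``X`` is the tidy
observation table the rest of the package uses (one row per measurement,
columns naming the variable, light, growth rate, limitation, and feeds);
``y`` is the measured value (or the table's ``value`` column).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConfigError
from .fitting import FitConfig, forward_evaluate, staged_fit
from .params import ModelParams
from .stoich import StoichRatios, default_ratios
from .synth import default_params


class AllocationModel(BaseEstimator, RegressorMixin):
    """Phytoplankton allocation/stoichiometry model with MH calibration.

    Parameters
    ----------
    init_params : ModelParams, dict or None
        Starting point of the chain (the 11 free parameters plus fixed
        pools).  None uses the packaged synthetic default organism.
    ratios : StoichRatios or None
        Elemental conversion constants; None uses the defaults.
    steps : tuple of int
        Chain length per calibration stage.
    proposal_scale : float
        Half-width of the uniform multiplicative proposal (0.2 = +/-20%).
    seed : int
        Seed for the single RNG driving all stages.
    sigma_frac : float
        Fallback fraction of the data range used as sigma_k when the table
        carries no sigma column and no replicates.
    stages : tuple of int
        Which stages to run (subset of (1, 2, 3)).

    Attributes
    ----------
    params_ : ModelParams
        Best parameter set found over all stage chains.
    best_error_ : float
        Total normalized error of ``params_`` on the fitting data.
    result_ : FitResult
        Full chain record (accepted states, error traces, diagnostics).
    acceptance_rate_ : float
        Accepted fraction of proposals, pooled over stages.
    """

    def __init__(self, init_params=None, ratios: StoichRatios | None = None,
                 steps=(20000, 20000, 20000), proposal_scale: float = 0.2,
                 seed: int = 0, sigma_frac: float = 0.1,
                 stages=(1, 2, 3)):
        self.init_params = init_params
        self.ratios = ratios
        self.steps = steps
        self.proposal_scale = proposal_scale
        self.seed = seed
        self.sigma_frac = sigma_frac
        self.stages = stages

    def _resolved_init(self) -> ModelParams:
        p = self.init_params
        if p is None:
            return default_params()
        if isinstance(p, ModelParams):
            return p
        if isinstance(p, dict):
            return ModelParams.from_dict(p)
        raise ConfigError("init_params must be ModelParams, dict or None")

    def _resolved_ratios(self) -> StoichRatios:
        return self.ratios if self.ratios is not None else default_ratios()

    def fit(self, X: pd.DataFrame, y=None) -> "AllocationModel":
        """Calibrate the free parameters against an observation table."""
        X = pd.DataFrame(X)
        if y is not None:
            X = X.copy()
            X["value"] = np.asarray(y, dtype=float)
        config = FitConfig(
            init_params=self._resolved_init(),
            steps=tuple(self.steps),
            proposal_scale=self.proposal_scale,
            seed=self.seed,
            sigma_frac=self.sigma_frac,
            stages=tuple(self.stages),
        )
        result = staged_fit(X, config, self._resolved_ratios())
        self.result_ = result
        self.params_ = result.best_params
        self.best_error_ = result.best_error
        self.acceptance_rate_ = result.acceptance_rate
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Forward-model values for each observation row.

        Uses the calibrated parameters when fitted, else the initial ones,
        so the estimator doubles as a plain forward simulator.
        """
        params = getattr(self, "params_", None) or self._resolved_init()
        return forward_evaluate(params, pd.DataFrame(X), self._resolved_ratios())
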