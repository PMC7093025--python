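"""Parameter-recovery experiments on synthetic chemostat data.

These are the package's own end-to-end validation procedures: generate a
dataset from the default organism under the default experiment design,
start the staged calibration from a randomly perturbed initial guess
(truth times an independent uniform factor in [0.5, 2] per free
parameter), and measure how closely the chain recovers the generating
parameters.  Used by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .fitting import FitConfig, FitResult, staged_fit
from .params import CHLOROPHYLL_PARAMS, FREE_PARAMS, ModelParams
from .synth import DesignSpec, default_params, generate, generate_noiseless

#: Step budget of the full staged recovery experiment (total 1e5 MH steps,
#: split across the chlorophyll, nitrogen/carbon, and phosphorus blocks).
FULL_RECOVERY_STEPS = (20000, 50000, 30000)


def perturbed_init(truth: ModelParams, names, rng: np.random.Generator) -> ModelParams:
    return truth.replace(
        **{k: getattr(truth, k) * rng.uniform(0.5, 2.0) for k in names}
    )


def relative_errors(fitted: ModelParams, truth: ModelParams, names) -> dict:
    return {k: abs(getattr(fitted, k) / getattr(truth, k) - 1.0) for k in names}


def stage1_noiseless_recovery(
    seed: int, steps: int = 20000, truth: ModelParams | None = None,
    design: DesignSpec | None = None,
) -> tuple[dict, FitResult]:
    """Recover the chlorophyll parameters from noise-free data.

    Returns the per-parameter relative errors and the fit result.
    """
    truth = truth or default_params()
    design = design or DesignSpec(seed=seed)
    data = generate_noiseless(truth, design)
    rng = np.random.default_rng(seed)
    init = perturbed_init(truth, CHLOROPHYLL_PARAMS, rng)
    result = staged_fit(
        data, FitConfig(init_params=init, steps=(steps, 0, 0), stages=(1,),
                        seed=seed)
    )
    return relative_errors(result.best_params, truth, CHLOROPHYLL_PARAMS), result


def staged_noisy_recovery(
    seed: int, steps: tuple[int, int, int] = FULL_RECOVERY_STEPS,
    truth: ModelParams | None = None, design: DesignSpec | None = None,
) -> tuple[dict, FitResult]:
    """Recover all 11 free parameters from one noisy synthetic dataset."""
    truth = truth or default_params()
    design = design or DesignSpec(seed=seed)
    data = generate(truth, design)
    rng = np.random.default_rng(seed)
    init = perturbed_init(truth, FREE_PARAMS, rng)
    result = staged_fit(data, FitConfig(init_params=init, steps=steps, seed=seed))
    return relative_errors(result.best_params, truth, FREE_PARAMS), result


def repeated_recovery(base_seed: int, n_seeds: int = 5,
                      steps: tuple[int, int, int] = FULL_RECOVERY_STEPS):
    """Run the full recovery over several seeds.

    Returns ``(median_rel_err, per_seed)``: the per-parameter median
    relative error across seeds, and the list of per-seed dicts.
    """
    per_seed = []
    for k in range(n_seeds):
        errs, _ = staged_noisy_recovery(base_seed + k, steps=steps)
        per_seed.append(errs)
    median = {
        name: float(np.median([e[name] for e in per_seed])) for name in FREE_PARAMS
    }
    return median, per_seed
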