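"""Latent oxidative-load index.

Each agent's unitless oxidative burden combines daily cannabis exposure,
sex, and (inverted) diet quality through a fixed linear index

    L_i = alpha_x * X_i + alpha_sex * sex_i + alpha_diet * (2 - diet_i) + eps_i

with eps_i ~ N(0, sigma_eps) an additive error term. Higher exposure, female
sex (coded 1), and poorer diet each increase the index. L is a heuristic
composite used only to propagate relative oxidative-stress differences; it is
not scaled to any biomarker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigError, StateError

__all__ = ["OxloadCoeffs", "compute_oxidative_load"]

_BASELINE_COLS = ("exposure", "sex", "diet")


@dataclass(frozen=True)
class OxloadCoeffs:
    """Linear coefficients of the oxidative-load index.

    ``alpha_x`` has units 1/(g/day); the others are unitless. ``alpha_x`` is
    fixed to 1 in the shipped configuration to pin the scale of L (the alphas
    and the outcome betas are otherwise jointly unidentified).
    """

    alpha_x: float = 1.0
    alpha_sex: float = 0.5
    alpha_diet: float = 0.25
    sigma_eps: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_x", "alpha_sex", "alpha_diet", "sigma_eps"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"OxloadCoeffs.{name} must be finite")
        if self.sigma_eps < 0:
            raise ConfigError("OxloadCoeffs.sigma_eps must be >= 0")


def compute_oxidative_load(
    cohort: pd.DataFrame, coeffs: OxloadCoeffs, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill the ``oxload`` column from the baseline columns.

    Standard-normal noise is drawn once per agent and scaled by ``sigma_eps``,
    so the generator state advances identically regardless of the coefficient
    values (common-random-number contract).
    """
    missing = [c for c in _BASELINE_COLS if c not in cohort.columns]
    if missing:
        raise StateError(f"baseline columns missing: {missing}")
    z = rng.standard_normal(len(cohort))
    out = cohort.copy()
    out["oxload"] = (
        coeffs.alpha_x * cohort["exposure"].to_numpy()
        + coeffs.alpha_sex * cohort["sex"].to_numpy()
        + coeffs.alpha_diet * (2.0 - cohort["diet"].to_numpy())
        + coeffs.sigma_eps * z
    )
    return out
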