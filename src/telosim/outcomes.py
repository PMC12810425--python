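"""Week-24 outcome propagation.

Baseline state is pushed forward 24 weeks through two linear channels driven
by the oxidative-load index L:

* follicular density:  D24_i = D0_i - beta_D * L_i + eta_i, floored at 0.
  Week-24 density is deliberately NOT re-truncated to the healthy-scalp range
  — sub-150 values are the early-miniaturization signal of interest.
* symptom severity: the agent's baseline latent severity is shifted by
  + beta_S * L_i + upsilon_i and the Likert items are regenerated with the
  same thresholds and item correlation (fresh item noise). Regenerating at
  the item level is what makes Week-24 internal consistency and
  baseline-to-Week-24 test-retest reliability well-defined quantities.

Exposure is also binned into the four NSDUH-style strata used by the ANCOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigError, DomainError, StateError
from .distributions import LikertSpec, likert_totals, sample_likert_items

__all__ = [
    "OutcomeCoeffs",
    "propagate_week24",
    "categorize_exposure",
    "EXPOSURE_CATEGORIES",
]

EXPOSURE_CATEGORIES = ("non", "light", "moderate", "heavy")


@dataclass(frozen=True)
class OutcomeCoeffs:
    """Week-24 linear outcome coefficients.

    ``beta_D`` is in hairs/cm² per unit L; ``beta_S`` in latent-severity SDs
    per unit L. Both are constrained non-negative — the harm direction (density
    loss, severity gain) is carried by the signs in the propagation formulas.
    """

    beta_D: float = 10.0
    beta_S: float = 0.5
    sigma_eta: float = 5.0
    sigma_upsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.beta_D < 0 or self.beta_S < 0:
            raise ConfigError("OutcomeCoeffs: beta_D and beta_S must be >= 0")
        if self.sigma_eta < 0 or self.sigma_upsilon < 0:
            raise ConfigError("OutcomeCoeffs: noise SDs must be >= 0")


def propagate_week24(
    cohort: pd.DataFrame,
    coeffs: OutcomeCoeffs,
    likert: LikertSpec,
    rng: np.random.Generator,
    likert_rng: np.random.Generator | None = None,
    cutpoints: tuple[float, float] = (0.5, 1.5),
    cap: float = 5.0,
) -> pd.DataFrame:
    """Fill Week-24 columns; requires ``oxload`` to be present.

    ``rng`` supplies the outcome noise (eta, upsilon); ``likert_rng`` (defaults
    to ``rng``) supplies the fresh Week-24 item noise. Noise is drawn as
    standard normals and scaled, so stream consumption is coefficient-free.
    """
    if "oxload" not in cohort.columns:
        raise StateError("oxload column missing: run compute_oxidative_load first")
    n = len(cohort)
    if likert_rng is None:
        likert_rng = rng
    L = cohort["oxload"].to_numpy()

    eta = coeffs.sigma_eta * rng.standard_normal(n)
    ups = coeffs.sigma_upsilon * rng.standard_normal(n)

    out = cohort.copy()
    d24 = cohort["density_baseline"].to_numpy() - coeffs.beta_D * L + eta
    out["density_week24"] = np.maximum(d24, 0.0)

    latent24 = cohort["latent_baseline"].to_numpy() + coeffs.beta_S * L + ups
    items24 = sample_likert_items(likert, latent24, likert_rng)
    for j in range(likert.n_items):
        out[f"sahl_wk24_item_{j + 1}"] = items24[:, j]
    out["sahl_total_week24"] = likert_totals(likert, items24)
    out["exposure_category"] = categorize_exposure(
        cohort["exposure"].to_numpy(), cutpoints=cutpoints, cap=cap
    )
    return out


def categorize_exposure(
    X: np.ndarray | float,
    cutpoints: tuple[float, float] = (0.5, 1.5),
    cap: float = 5.0,
) -> np.ndarray | str:
    """Bin exposure into non / light / moderate / heavy.

    non iff X == 0; light iff 0 < X <= lo; moderate iff lo < X <= hi;
    heavy iff X > hi (half-open upper intervals). Raises for X outside [0, cap].
    """
    lo, hi = cutpoints
    if not (0.0 < lo < hi < cap):
        raise ConfigError("cutpoints must satisfy 0 < lo < hi < cap")
    x = np.asarray(X, dtype=float)
    if np.any(x < 0.0) or np.any(x > cap):
        raise DomainError(f"exposure values must lie in [0, {cap}]")
    cats = np.select(
        [x == 0.0, x <= lo, x <= hi],
        ["non", "light", "moderate"],
        default="heavy",
    )
    if np.isscalar(X) or np.ndim(X) == 0:
        return str(cats)
    return cats
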