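"""Cohort initialization: demographics, baseline density, baseline SAHL.

One row per simulated agent. Baseline columns are a function of the marginal
specs and the demographic parameters only — the structural coefficients never
touch them, which the named-substream seeding guarantees.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .distributions import likert_totals, sample_likert_items, sample_trunc_normal, sample_exposure
from .rng import RNGPolicy

__all__ = ["COLUMN_ORDER", "init_cohort", "cohort_columns"]


def cohort_columns(n_items: int = 9) -> list[str]:
    """Canonical column order of a fully propagated cohort table."""
    base = [
        "agent_id", "age", "sex", "diet", "exposure", "density_baseline",
    ]
    base += [f"sahl_base_item_{j + 1}" for j in range(n_items)]
    base += ["sahl_total_baseline", "latent_baseline", "oxload", "density_week24"]
    base += [f"sahl_wk24_item_{j + 1}" for j in range(n_items)]
    base += ["sahl_total_week24", "exposure_category"]
    return base


COLUMN_ORDER = cohort_columns()


def init_cohort(config: SimulationConfig, rng: RNGPolicy) -> pd.DataFrame:
    """Baseline cohort table (one row per agent, Week-24 columns absent).

    Age is normal, rounded to whole years and clipped to the young-adult
    window; sex is Bernoulli (1 = female); diet quality is ordinal
    poor/fair/good = 0/1/2. Baseline density, exposure, and the item-level
    SAHL battery come from their marginal samplers; the baseline latent
    severity driving the items is standard normal. The SAHL total is the sum
    of the three domain means.
    """
    n = config.cohort_size
    demo = config.demographics

    g = rng.stream("demographics")
    age = np.clip(
        np.rint(demo.age_mean + demo.age_sd * g.standard_normal(n)),
        demo.age_min, demo.age_max,
    ).astype(np.int64)
    sex = (g.random(n) < demo.p_female).astype(np.int64)
    diet = g.choice(3, size=n, p=np.asarray(demo.diet_probs, dtype=float))

    density = sample_trunc_normal(config.density, n, rng.stream("density"))
    exposure = sample_exposure(config.exposure, n, rng.stream("exposure"))

    g_lik = rng.stream("likert_baseline")
    latent = g_lik.standard_normal(n)
    items = sample_likert_items(config.likert, latent, g_lik)

    df = pd.DataFrame({
        "agent_id": np.arange(n, dtype=np.int64),
        "age": age,
        "sex": sex,
        "diet": diet.astype(np.int64),
        "exposure": exposure,
        "density_baseline": density,
    })
    for j in range(config.likert.n_items):
        df[f"sahl_base_item_{j + 1}"] = items[:, j]
    df["sahl_total_baseline"] = likert_totals(config.likert, items)
    df["latent_baseline"] = latent
    return df
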