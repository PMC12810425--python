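"""End-to-end pipeline: init -> oxidative load -> Week-24 -> report.

Also owns the CSV contract for the cohort table (fixed column order, floats
at 6 significant digits) so identical seeds yield byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .analysis import build_report
from .cohort import cohort_columns, init_cohort
from .config import SimulationConfig
from .outcomes import propagate_week24
from .oxload import compute_oxidative_load
from .rng import RNGPolicy

__all__ = [
    "simulate_cohort",
    "analyze_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

_FLOAT_COLS = (
    "exposure", "density_baseline", "sahl_total_baseline", "latent_baseline",
    "oxload", "density_week24", "sahl_total_week24",
)


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Run the full generative pipeline and return the propagated cohort."""
    rng = RNGPolicy(config.seed if seed is None else seed)
    df = init_cohort(config, rng)
    df = compute_oxidative_load(df, config.oxload, rng.stream("oxload_noise"))
    df = propagate_week24(
        df,
        config.outcomes,
        config.likert,
        rng.stream("outcome_noise"),
        likert_rng=rng.stream("likert_week24"),
        cutpoints=config.cutpoints,
        cap=config.exposure.cap,
    )
    return df[cohort_columns(config.likert.n_items)]


def analyze_cohort(df: pd.DataFrame, config: SimulationConfig | None = None,
                   provenance: dict | None = None) -> dict:
    likert = config.likert if config is not None else None
    return build_report(df, likert=likert, provenance=provenance)


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort with a stable column order and float format."""
    out = df.copy()
    for c in _FLOAT_COLS:
        if c in out.columns:
            out[c] = out[c].map(lambda v: f"{v:.6g}")
    out.to_csv(path, index=False, lineterminator="\n")


def read_cohort_csv(path: str | Path, n_items: int = 9) -> pd.DataFrame:
    """Read a cohort CSV, validating the schema.

    Week-24 columns may be absent (a baseline-only table); any other
    missing or unknown column is a schema error.
    """
    df = pd.read_csv(path)
    expected = cohort_columns(n_items)
    baseline = [c for c in expected
                if "wk24" not in c and "week24" not in c and c != "exposure_category"]
    missing_base = [c for c in baseline if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing_base or extra:
        raise ConfigError(
            f"cohort CSV schema mismatch; missing: {missing_base}, extra: {extra}"
        )
    return df


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     allow_nan=True) + "\n")
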