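"""End-to-end parameter-recovery experiments.

These functions run the full synthetic pipeline — cohort simulation,
image rendering, puncta detection, rectangle placement, density
computation, per-animal averaging and sham normalization — and report
the recovered cuff-ipsilateral percent of sham per endpoint.  They are
the package's reproduction of the source-study quantities and are what
the acceptance script and the recovery tests call.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import iter_cohort_sections, simulate_behavior_cohort
from .quantify import DetectionParams
from .roi import quantify_section
from .stats import aggregate_animals, normalize_to_sham
from .timecourse import TimecourseConfig

__all__ = [
    "quantify_cohort_day",
    "recover_histology_pct",
    "recover_behavior_pct",
]

log = logging.getLogger(__name__)


def quantify_cohort_day(
    config: TimecourseConfig,
    day: int,
    seed: int,
    params: dict[str, DetectionParams] | None = None,
) -> pd.DataFrame:
    """Simulate and quantify every section of one time point.

    Returns the tidy section-level density table (8 rows per section).
    Sections are rendered, quantified and discarded one at a time to
    bound memory.
    """
    out = []
    for s in iter_cohort_sections(config, day, seed, render=True):
        df, _ = quantify_section(
            s.micrograph,
            s.geometry,
            params=params,
            sham=(s.group == "sham"),
            meta=dict(day=s.day, group=s.group, animal=s.animal_id, section=s.section_index),
        )
        out.append(df)
        log.debug("quantified %s section %d", s.animal_id, s.section_index)
    return pd.concat(out, ignore_index=True)


def recover_histology_pct(
    config: TimecourseConfig,
    day: int,
    seed: int,
    n_rep: int = 1,
    params: dict[str, DetectionParams] | None = None,
) -> dict[tuple[str, str], float]:
    """Recovered cuff-ipsilateral percent of sham by (marker, lamina).

    Each replicate simulates an independent cohort (seeded from
    ``seed``), averages the six sections to one value per animal, and
    normalizes the cuff ipsilateral mean by the sham ipsilateral mean;
    replicates are averaged.
    """
    acc: dict[tuple[str, str], list[float]] = {}
    for rep in range(n_rep):
        records = quantify_cohort_day(config, day, int(seed) + 100_003 * rep, params)
        per_animal = aggregate_animals(records, "density")
        norm = normalize_to_sham(per_animal, value_col="density")
        cuff = norm[(norm["group"] == "cuff") & (norm["side"] == "ipsilateral")]
        for _, row in cuff.iterrows():
            acc.setdefault((row["marker"], row["lamina"]), []).append(row["mean_pct_of_sham"])
    return {k: float(np.mean(v)) for k, v in acc.items()}


def recover_behavior_pct(
    config: TimecourseConfig,
    day: int,
    seed: int,
    n_rep: int = 20,
) -> dict[str, float]:
    """Recovered cuff percent of sham for the behavioural endpoints.

    Each replicate simulates one behavioural cohort (``behavior_n``
    animals per group) at the given day, scores every animal and takes
    the cuff group mean as a percent of the sham group mean; replicates
    are averaged.  Replication is cheap here, so the default of 20
    bounds the staircase estimator's sampling noise.
    """
    acc: dict[str, list[float]] = {}
    for rep in range(n_rep):
        df = simulate_behavior_cohort(config, int(seed) + 100_003 * rep, days=(day,))
        for endpoint, sub in df.groupby("endpoint"):
            sham = sub.loc[sub["group"] == "sham", "value"].mean()
            cuff = sub.loc[sub["group"] == "cuff", "value"].mean()
            acc.setdefault(endpoint, []).append(100.0 * cuff / sham)
    return {k: float(np.mean(v)) for k, v in acc.items()}
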