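"""Packaged injury/recovery time-course and cohort configuration.

The defaults encode the study conditions the generator emulates: a
unilateral cuff constriction of the sciatic nerve with histology at
days 5-56 and behaviour at days 5-56 including day 28.  Cuff
ipsilateral percent-of-sham values at days 21 and 56 (histology), day
21 (von Frey) and day 28 (Hargreaves) are the values printed in the
source study; the remaining days follow the described shape of the
curves (progressive decline from day 5, nadir at day 21, partial
recovery by day 56) and are approximate.

Behavioural percentages are *assay-level* (measured) contrasts: the
printed von Frey percentage is an output of the up-down estimator,
which is biased at the default psychometric slope, so the generator
derives latent thresholds by inverting the assay's operating
characteristic (see :func:`dorsalhorn.behavior.latent_threshold_for_measured`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import GeometryConfig
from .synth import NoiseModel

__all__ = [
    "HISTOLOGY_DAYS",
    "BEHAVIOR_DAYS",
    "TimecourseConfig",
    "DEFAULT_TIMECOURSE",
]

HISTOLOGY_DAYS = (5, 7, 10, 14, 21, 42, 56)
BEHAVIOR_DAYS = (5, 7, 10, 14, 21, 28, 42, 56)

#: sham baseline puncta densities, puncta per 100 μm², by (marker, lamina)
DEFAULT_BASELINE_DENSITY = {
    ("IB4", "LII"): 25.0,
    ("IB4", "LI"): 4.0,
    ("GAD65", "LII"): 25.0,
    ("GAD65", "LI"): 25.0,
}

#: cuff ipsilateral percent-of-sham by (day, marker, lamina); days 21 and
#: 56 are printed values, other days follow the described curve shapes
DEFAULT_CUFF_IPSI_PCT = {
    # IB4 in the LII lesion zone: severe depletion, nadir day 21
    (5, "IB4", "LII"): 60.0,
    (7, "IB4", "LII"): 40.0,
    (10, "IB4", "LII"): 20.0,
    (14, "IB4", "LII"): 8.0,
    (21, "IB4", "LII"): 1.5,
    (42, "IB4", "LII"): 30.0,
    (56, "IB4", "LII"): 52.1,
    # GAD65 in LII: slower onset, nadir day 21, incomplete recovery
    (5, "GAD65", "LII"): 90.0,
    (7, "GAD65", "LII"): 85.0,
    (10, "GAD65", "LII"): 65.0,
    (14, "GAD65", "LII"): 50.0,
    (21, "GAD65", "LII"): 34.1,
    (42, "GAD65", "LII"): 85.0,
    (56, "GAD65", "LII"): 72.0,
    # GAD65 in LI: milder loss, recovery by day 42
    (5, "GAD65", "LI"): 92.0,
    (7, "GAD65", "LI"): 88.0,
    (10, "GAD65", "LI"): 80.0,
    (14, "GAD65", "LI"): 72.0,
    (21, "GAD65", "LI"): 63.1,
    (42, "GAD65", "LI"): 95.0,
    (56, "GAD65", "LI"): 95.0,
}

#: behavioural cuff-ipsilateral percent of sham (measured scale)
DEFAULT_CUFF_VF_PCT = {5: 85.0, 7: 75.0, 10: 60.0, 14: 40.0, 21: 16.3, 28: 25.0, 42: 60.0, 56: 100.0}
DEFAULT_CUFF_HG_PCT = {5: 95.0, 7: 92.0, 10: 88.0, 14: 82.0, 21: 75.0, 28: 70.1, 42: 85.0, 56: 100.0}


@dataclass(frozen=True)
class TimecourseConfig:
    """Cohort sizes, baselines and the injury/recovery time-course.

    ``animal_cv`` and ``section_cv`` are log-normal coefficients of
    variation of per-animal and per-section multiplicative density
    factors.  ``coupling`` is the weight of the per-animal factor shared
    between the IB4 and GAD65 channels (1 = fully shared, 0 =
    independent), which tunes the cross-marker correlation.
    """

    days: tuple[int, ...] = BEHAVIOR_DAYS
    histology_days: tuple[int, ...] = HISTOLOGY_DAYS
    sham_n: int = 5
    cuff_n: int = 6
    sections_per_animal: int = 6
    behavior_n: int = 10  # animals per group in the behavioural cohort

    baseline_density: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_DENSITY))
    cuff_ipsi_pct: dict = field(default_factory=lambda: dict(DEFAULT_CUFF_IPSI_PCT))
    cuff_contra_pct: dict = field(default_factory=dict)  # default: 100%

    animal_cv: float = 0.05
    section_cv: float = 0.05
    coupling: float = 0.7
    area_cv: float = 0.5

    sham_vf_threshold_g: float = 10.0
    sham_hg_latency_s: float = 10.0
    vf_slope: float = 5.0
    hg_trial_sd_s: float = 1.5
    cuff_vf_pct: dict = field(default_factory=lambda: dict(DEFAULT_CUFF_VF_PCT))
    cuff_hg_pct: dict = field(default_factory=lambda: dict(DEFAULT_CUFF_HG_PCT))

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self):
        for key, pct in list(self.cuff_ipsi_pct.items()) + list(self.cuff_contra_pct.items()):
            if pct < 0:
                raise ValueError(f"percentage for {key} must be >= 0")
        if self.sections_per_animal < 1:
            raise ValueError("sections_per_animal must be >= 1")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")

    def pct_of_sham(self, day: int, group: str, side: str, marker: str, lamina: str) -> float:
        """Nominal percent-of-sham density for one stratum (sham = 100)."""
        if group == "sham":
            return 100.0
        table = self.cuff_ipsi_pct if side == "ipsilateral" else self.cuff_contra_pct
        return float(table.get((day, marker, lamina), 100.0))

    def true_density(self, day, group, side, marker, lamina) -> float:
        base = self.baseline_density.get((marker, lamina), 0.0)
        return base * self.pct_of_sham(day, group, side, marker, lamina) / 100.0


DEFAULT_TIMECOURSE = TimecourseConfig()
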