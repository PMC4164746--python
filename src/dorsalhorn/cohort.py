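"""Seeded cohort simulation: sections with ground truth, and behaviour.

Per-animal sub-seeds are derived deterministically from
``(seed, day, group, animal index)``, so a cohort is reproducible
animal-by-animal.  Biological and technical variability enter as
mean-preserving log-normal multiplicative factors: one per animal and
marker (with a configurable fraction shared between the two markers,
which sets the cross-marker correlation) and one per section and
marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import (
    estimate_threshold,
    hargreaves_latency,
    latent_threshold_for_measured,
    measured_updown_mean,
    simulate_hargreaves_trials,
    simulate_updown_trials,
)
from .geometry import Rect, SectionGeometry, generate_geometry
from .synth import CHANNELS, MEAN_AREA_UM2, Micrograph, PunctaField, render_micrograph, sample_puncta
from .timecourse import TimecourseConfig

__all__ = [
    "SectionSample",
    "iter_cohort_sections",
    "simulate_behavior_cohort",
    "cohort_animals",
]

_GROUPS = ("sham", "cuff")


@dataclass
class SectionSample:
    """One simulated section: image, geometry and ground truth."""

    day: int
    group: str
    animal_id: str
    section_index: int
    geometry: SectionGeometry  # ipsilateral horn; .mirrored() is the other
    fields: dict  # channel -> list[PunctaField], both sides pooled
    micrograph: Micrograph | None
    truth: pd.DataFrame  # side x lamina x marker nominal/realized densities


def cohort_animals(config: TimecourseConfig) -> list[tuple[str, str]]:
    """(group, animal_id) pairs of the histology cohort."""
    out = [("sham", f"sham{i + 1:02d}") for i in range(config.sham_n)]
    out += [("cuff", f"cuff{i + 1:02d}") for i in range(config.cuff_n)]
    return out


def _animal_factors(config: TimecourseConfig, rng: np.random.Generator) -> dict:
    """Mean-preserving log-normal per-marker factors with shared component."""
    sig = np.sqrt(np.log1p(config.animal_cv**2))
    c = config.coupling
    u = rng.standard_normal(3)  # shared, IB4-specific, GAD65-specific
    mix = {
        "IB4": c * u[0] + np.sqrt(1.0 - c**2) * u[1],
        "GAD65": c * u[0] + np.sqrt(1.0 - c**2) * u[2],
    }
    return {m: float(np.exp(sig * z - sig**2 / 2.0)) for m, z in mix.items()}


def _section_factors(config: TimecourseConfig, rng: np.random.Generator) -> dict:
    sig = np.sqrt(np.log1p(config.section_cv**2))
    return {m: float(np.exp(sig * rng.standard_normal() - sig**2 / 2.0)) for m in CHANNELS}


def _band_fields(
    geom: SectionGeometry,
    config: TimecourseConfig,
    day: int,
    group: str,
    marker: str,
    factor: float,
    rng: np.random.Generator,
) -> list[PunctaField]:
    """Punctum fields of one marker in one horn, lesion-modulated."""
    fields = []
    mean_area = MEAN_AREA_UM2[marker]
    lz = geom.lesion_zone
    x_lo, x_hi = min(lz.x_um, lz.x1_um), max(lz.x_um, lz.x1_um)
    for lamina in ("LI", "LII"):
        band = geom.band_rect(lamina)
        base = config.baseline_density.get((marker, lamina), 0.0)
        if base <= 0:
            continue
        pct = config.pct_of_sham(day, group, geom.side, marker, lamina)
        outside_d = base * factor
        inside_d = base * pct / 100.0 * factor
        if pct == 100.0:
            fields.append(sample_puncta(band, outside_d, mean_area, config.area_cv, rng, marker))
            continue
        # split the band at the lesion's medio-lateral interval
        pieces = [
            (Rect(band.x_um, band.y_um, x_lo - band.x_um, band.height_um), outside_d),
            (Rect(x_lo, band.y_um, x_hi - x_lo, band.height_um), inside_d),
            (Rect(x_hi, band.y_um, band.x1_um - x_hi, band.height_um), outside_d),
        ]
        for rect, d in pieces:
            if rect.width_um > 1e-9:
                fields.append(sample_puncta(rect, d, mean_area, config.area_cv, rng, marker))
    return fields


def _truth_rows(config, day, group, animal_id, section_index, factors):
    rows = []
    for side in ("ipsilateral", "contralateral"):
        for marker in CHANNELS:
            for lamina in ("LI", "LII"):
                base = config.baseline_density.get((marker, lamina), 0.0)
                pct = config.pct_of_sham(day, group, side, marker, lamina)
                rows.append(
                    dict(
                        day=day,
                        group=group,
                        animal=animal_id,
                        section=section_index,
                        side=side,
                        marker=marker,
                        lamina=lamina,
                        true_density_nominal=base * pct / 100.0,
                        true_density=base * pct / 100.0 * factors[marker],
                        pct_of_sham_nominal=pct,
                    )
                )
    return pd.DataFrame(rows)


def iter_cohort_sections(
    config: TimecourseConfig,
    day: int,
    seed: int,
    render: bool = True,
):
    """Yield every section of the histology cohort for one time point.

    Sections are yielded animal by animal; with ``render=False`` only
    geometry, fields and ground truth are produced (for count-level
    tests that bypass the imaging stage).
    """
    for a_idx, (group, animal_id) in enumerate(cohort_animals(config)):
        a_seq = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, int(day), a_idx])
        a_rng = np.random.default_rng(a_seq)
        afac = _animal_factors(config, a_rng)
        for s_idx in range(config.sections_per_animal):
            s_rng = np.random.default_rng(
                np.random.SeedSequence([int(seed) & 0x7FFFFFFF, int(day), a_idx, s_idx])
            )
            geom = generate_geometry(
                config.geometry, seed=int(s_rng.integers(1 << 31))
            )
            sfac = _section_factors(config, s_rng)
            factors = {m: afac[m] * sfac[m] for m in CHANNELS}
            fields: dict[str, list[PunctaField]] = {m: [] for m in CHANNELS}
            for side_geom in (geom, geom.mirrored()):
                for marker in CHANNELS:
                    fields[marker].extend(
                        _band_fields(side_geom, config, day, group, marker, factors[marker], s_rng)
                    )
            micro = render_micrograph(geom, fields, config.noise, s_rng) if render else None
            yield SectionSample(
                day=day,
                group=group,
                animal_id=animal_id,
                section_index=s_idx,
                geometry=geom,
                fields=fields,
                micrograph=micro,
                truth=_truth_rows(config, day, group, animal_id, s_idx, factors),
            )


def _latent_vf(config: TimecourseConfig, day: int, group: str) -> float:
    """Latent 50% threshold whose measured group mean hits the configured
    percent of the measured sham mean (the printed values are assay-level)."""
    if group == "sham":
        return config.sham_vf_threshold_g
    m_sham = measured_updown_mean(config.sham_vf_threshold_g, config.vf_slope)
    pct = config.cuff_vf_pct.get(day, 100.0)
    return latent_threshold_for_measured(pct / 100.0 * m_sham, config.vf_slope)


def simulate_behavior_cohort(
    config: TimecourseConfig,
    seed: int,
    days: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Simulate and score the behavioural cohort (ipsilateral paw).

    Returns one row per animal x day x endpoint with the scored value
    (von Frey 50% threshold in grams with its response pattern, or the
    mean Hargreaves latency in seconds).
    """
    days = tuple(days) if days is not None else config.days
    sig = np.sqrt(np.log1p(config.animal_cv**2))
    rows = []
    for day in days:
        for g_idx, group in enumerate(_GROUPS):
            t_vf = _latent_vf(config, day, group)
            t_hg = config.sham_hg_latency_s * (
                config.cuff_hg_pct.get(day, 100.0) / 100.0 if group == "cuff" else 1.0
            )
            for a in range(config.behavior_n):
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 1000 + int(day), g_idx, a])
                )
                jit_vf = float(np.exp(sig * rng.standard_normal() - sig**2 / 2.0))
                jit_hg = float(np.exp(sig * rng.standard_normal() - sig**2 / 2.0))
                seq = simulate_updown_trials(t_vf * jit_vf, config.vf_slope, seed=rng)
                thr = estimate_threshold(seq)
                trials = simulate_hargreaves_trials(t_hg * jit_hg, config.hg_trial_sd_s, seed=rng)
                lat = hargreaves_latency(trials)
                aid = f"{group}{a + 1:02d}"
                rows.append(
                    dict(day=day, group=group, animal=aid, endpoint="vf_threshold_g",
                         value=thr.threshold_g, detail=seq.serialize())
                )
                rows.append(
                    dict(day=day, group=group, animal=aid, endpoint="hg_latency_s",
                         value=lat, detail=";".join(f"{t:.2f}" for t in trials))
                )
    return pd.DataFrame(rows)
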