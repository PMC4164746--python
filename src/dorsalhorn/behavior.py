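"""Behavioural endpoints: von Frey up-down threshold and Hargreaves latency.

The 50% mechanical withdrawal threshold follows the up-down staircase
over the filament set (0.6, 1, 1.4, 2, 4, 6, 8, 10, 15, 26 g): a
withdrawal moves to the next weaker filament, a non-response to the next
stronger one, and the session ends four presentations after the first
reversal (or at a bound of the set).  The threshold is

    T(g) = 10^(Xf + k*delta) / 10^4

with ``Xf`` the final filament in 10^4-scaled log10 units
(``log10(grams) + 4``), ``delta = 0.224`` the nominal log spacing, and
``k`` the Dixon pattern value.  ``k`` is obtained by maximizing the
Dixon likelihood of the response sequence under a normal psychometric
function with spread ``delta`` — the construction from which the
published pattern tables were derived — so every legal pattern,
tabulated or not, gets a value.

Thermal (Hargreaves) latency is the arithmetic mean of up to three
radiant-heat trials, each censored at 20.48 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtr

__all__ = [
    "FILAMENTS_G",
    "DELTA",
    "HARGREAVES_CUTOFF_S",
    "VonFreySequence",
    "ThresholdResult",
    "simulate_updown_trials",
    "simulate_hargreaves_trials",
    "estimate_threshold",
    "hargreaves_latency",
]

#: the von Frey filament set, grams, ascending
FILAMENTS_G = (0.6, 1.0, 1.4, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 26.0)

#: nominal mean log10 spacing between consecutive filaments
DELTA = 0.224

HARGREAVES_CUTOFF_S = 20.48

#: default starting filament for the staircase (mid-range, 2 g)
DEFAULT_START_G = 2.0

#: presentations collected after the first reversal before stopping
POST_REVERSAL_TRIALS = 4


@dataclass(frozen=True)
class VonFreySequence:
    """Ordered filament presentations with withdraw (True) / none (False)."""

    filaments_g: tuple[float, ...]
    responses: tuple[bool, ...]
    filament_set: tuple[float, ...] = FILAMENTS_G

    def __post_init__(self):
        if len(self.filaments_g) != len(self.responses):
            raise ValueError("filaments and responses must have equal length")
        for g in self.filaments_g:
            if g not in self.filament_set:
                raise ValueError(f"{g} g is not in the filament set")

    def __len__(self) -> int:
        return len(self.filaments_g)

    def pattern(self) -> str:
        """The response pattern string, X = withdrawal, 0 = none."""
        return "".join("X" if r else "0" for r in self.responses)

    def serialize(self) -> str:
        """Pattern plus filament indices, e.g. ``0X0X0|3,4,3,4,3``."""
        idx = ",".join(str(self.filament_set.index(g)) for g in self.filaments_g)
        return f"{self.pattern()}|{idx}"

    def validate_updown(self) -> None:
        """Check the up-down stepping rule at every consecutive pair."""
        idx = [self.filament_set.index(g) for g in self.filaments_g]
        for step, (i0, i1, r0) in enumerate(zip(idx, idx[1:], self.responses)):
            expected = i0 - 1 if r0 else i0 + 1
            expected = min(max(expected, 0), len(self.filament_set) - 1)
            if i1 != expected:
                raise ValueError(
                    f"presentation {step + 1} violates the up-down rule: "
                    f"{self.filaments_g[step]} g with "
                    f"{'withdrawal' if r0 else 'no withdrawal'} must be followed "
                    f"by {self.filament_set[expected]} g, got {self.filaments_g[step + 1]} g"
                )


@dataclass(frozen=True)
class ThresholdResult:
    threshold_g: float
    x_f: float  # final filament, log10(10^4 x grams)
    k: float
    delta: float = DELTA
    censored: str = "none"  # none | high | low
    pattern: str = ""


def simulate_updown_trials(
    true_threshold_g: float,
    psychometric_slope: float,
    filament_set: tuple[float, ...] = FILAMENTS_G,
    seed: int | np.random.Generator = 0,
    start_g: float | None = None,
) -> VonFreySequence:
    """Simulate one up-down session from a logistic psychometric function.

    ``P(withdraw | g) = expit(slope * (log10 g - log10 threshold))``;
    the staircase stops four presentations after the first reversal or on
    stepping past either end of the filament set.
    """
    if len(filament_set) == 0:
        raise ValueError("filament set must not be empty")
    if any(b <= a for a, b in zip(filament_set, filament_set[1:])):
        raise ValueError("filament set must be sorted ascending")
    if psychometric_slope <= 0:
        raise ValueError("psychometric_slope must be > 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xF7]))
    )
    logt = np.log10(true_threshold_g)
    if start_g is None:
        start_g = DEFAULT_START_G if DEFAULT_START_G in filament_set else filament_set[len(filament_set) // 2]
    i = filament_set.index(start_g)
    fil: list[float] = []
    res: list[bool] = []
    first_reversal = None
    while True:
        g = filament_set[i]
        p = expit(psychometric_slope * (np.log10(g) - logt))
        r = bool(rng.random() < p)
        fil.append(g)
        res.append(r)
        n = len(res)
        if first_reversal is None and n >= 2 and res[-1] != res[-2]:
            first_reversal = n - 1
        if first_reversal is not None and n - first_reversal >= POST_REVERSAL_TRIALS:
            break
        nxt = i - 1 if r else i + 1
        if nxt < 0 or nxt >= len(filament_set):
            break  # stepping past a bound ends the session
        i = nxt
    return VonFreySequence(tuple(fil), tuple(res), tuple(filament_set))


def simulate_hargreaves_trials(
    true_latency_s: float,
    trial_sd_s: float,
    n_trials: int = 3,
    cutoff_s: float = HARGREAVES_CUTOFF_S,
    seed: int | np.random.Generator = 0,
) -> list[float]:
    """Simulate radiant-heat withdrawal latencies, censored at the cutoff."""
    if true_latency_s <= 0:
        raise ValueError("true_latency_s must be > 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x46]))
    )
    lat = rng.normal(true_latency_s, trial_sd_s, size=n_trials) if trial_sd_s > 0 else np.full(n_trials, float(true_latency_s))
    lat = np.clip(lat, 0.05, cutoff_s)
    return [float(v) for v in lat]


def _dixon_k(window_log10g: np.ndarray, window_resp: np.ndarray, x_final_log10g: float, delta: float) -> float:
    """Dixon pattern value by maximum likelihood.

    Normal psychometric with mean μ and SD ``delta`` (log10 grams);
    ``k = (μ̂ − x_final)/delta``, clipped to ±3 (the tabulated range).
    """
    lo = window_log10g.min() - 3.0 * delta
    hi = window_log10g.max() + 3.0 * delta
    mu = np.linspace(lo, hi, 1201)
    z = (window_log10g[None, :] - mu[:, None]) / delta
    p = np.clip(ndtr(z), 1e-12, 1.0 - 1e-12)
    ll = np.where(window_resp[None, :], np.log(p), np.log1p(-p)).sum(axis=1)
    mu_hat = mu[np.argmax(ll)]
    return float(np.clip((mu_hat - x_final_log10g) / delta, -3.0, 3.0))


def updown_threshold_g(x_f: float, k: float, delta: float = DELTA) -> float:
    """The 50% threshold formula: ``10^(Xf + k*delta) / 10^4`` grams.

    ``x_f`` is the final filament in 10^4-scaled log10 units, i.e.
    ``log10(grams) + 4``.
    """
    return float(10.0 ** (x_f + k * delta) / 1e4)


def estimate_threshold(seq: VonFreySequence, delta: float = DELTA) -> ThresholdResult:
    """Score one up-down session with the 10^4-scaled log formula.

    Sessions without a reversal that end at a bound of the filament set
    are censored to that bound (26 g high, 0.6 g low).
    """
    if len(seq) < 1:
        raise ValueError("sequence must contain at least one presentation")
    seq.validate_updown()
    resp = np.array(seq.responses, dtype=bool)
    logg = np.log10(np.array(seq.filaments_g, dtype=float))
    g_final = seq.filaments_g[-1]
    x_f = np.log10(g_final) + 4.0
    pattern = seq.pattern()
    gmin, gmax = seq.filament_set[0], seq.filament_set[-1]

    if not resp.any() and g_final == gmax:
        return ThresholdResult(gmax, x_f, 0.0, delta, "high", pattern)
    if resp.all() and g_final == gmin:
        return ThresholdResult(gmin, x_f, 0.0, delta, "low", pattern)

    rev = np.nonzero(resp[1:] != resp[:-1])[0]
    if len(rev) == 0:
        # monotone walk that stopped at a bound without bracketing
        if resp[0]:
            return ThresholdResult(gmin, x_f, 0.0, delta, "low", pattern)
        return ThresholdResult(gmax, x_f, 0.0, delta, "high", pattern)

    # the whole sequence enters the likelihood: the monotone walk before
    # the first reversal brackets the threshold and discarding it biases
    # the estimate toward the starting filament
    k = _dixon_k(logg, resp, float(np.log10(g_final)), delta)
    thr = updown_threshold_g(x_f, k, delta)
    censored = "none"
    if thr > gmax:
        thr, censored = gmax, "high"
    elif thr < gmin:
        thr, censored = gmin, "low"
    return ThresholdResult(thr, x_f, k, delta, censored, pattern)


def hargreaves_latency(trials: list[float], cutoff_s: float = HARGREAVES_CUTOFF_S) -> float:
    """Mean withdrawal latency over 1-3 trials, all at or below the cutoff."""
    if not 1 <= len(trials) <= 3:
        raise ValueError("expected 1-3 trials")
    for t in trials:
        if t > cutoff_s + 1e-9:
            raise ValueError(f"trial latency {t} s exceeds the {cutoff_s} s cutoff")
    return float(np.mean(trials))


# ---------------------------------------------------------------------------
# Assay operating characteristic and latent-threshold calibration
# ---------------------------------------------------------------------------

_OC_CACHE: dict = {}

#: internal calibration seed; a fixed constant so the operating
#: characteristic is a reproducible property of the assay, not of a run
_CALIBRATION_SEED = 20481

def measured_updown_mean(
    true_threshold_g: float,
    psychometric_slope: float,
    filament_set: tuple[float, ...] = FILAMENTS_G,
    start_g: float | None = None,
    n_sessions: int = 4000,
) -> float:
    """Expected group-mean up-down estimate at a given latent threshold.

    Estimated by simulating ``n_sessions`` sessions with fixed internal
    seeds; this is the assay's operating characteristic m(t).  Because
    the staircase is bounded by the filament set and its psychometric
    function is shallow, m(t) differs systematically from t.
    """
    root = np.random.SeedSequence([_CALIBRATION_SEED, int(round(1e6 * np.log10(true_threshold_g))) & 0x7FFFFFFF])
    rngs = [np.random.default_rng(s) for s in root.spawn(n_sessions)]
    est = [
        estimate_threshold(
            simulate_updown_trials(true_threshold_g, psychometric_slope, filament_set, rng, start_g)
        ).threshold_g
        for rng in rngs
    ]
    return float(np.mean(est))


def latent_threshold_for_measured(
    target_measured_g: float,
    psychometric_slope: float,
    filament_set: tuple[float, ...] = FILAMENTS_G,
    start_g: float | None = None,
) -> float:
    """Latent threshold whose measured group mean equals the target.

    Inverts m(t) by monotone interpolation on a log-spaced grid spanning
    the filament range.  Used to encode printed (assay-level) behavioural
    percentages as generator truths.
    """
    key = (round(psychometric_slope, 6), filament_set, start_g)
    if key not in _OC_CACHE:
        grid = np.geomspace(filament_set[0] * 0.8, filament_set[-1] * 0.9, 25)
        m = np.array([measured_updown_mean(t, psychometric_slope, filament_set, start_g) for t in grid])
        order = np.argsort(m)
        _OC_CACHE[key] = (m[order], grid[order])
    m_grid, t_grid = _OC_CACHE[key]
    if not (m_grid[0] <= target_measured_g <= m_grid[-1]):
        raise ValueError(
            f"target measured threshold {target_measured_g} g outside the calibratable range "
            f"[{m_grid[0]:.2f}, {m_grid[-1]:.2f}] g"
        )
    return float(np.interp(target_measured_g, m_grid, t_grid))
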