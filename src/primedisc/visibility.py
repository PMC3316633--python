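"""Signal-detection analysis of the prime-visibility tests.

Two post-experiment tests check that the masked primes were subliminal:

* detection — an image (apple logo or cup) is present on half the trials;
  "yes" on an image trial is a hit, "yes" on a blank trial a false alarm;
* identification — one of four masked images is shown each trial and the
  participant picks one of the four; choosing "apple" when the apple logo
  was shown is a hit, choosing "apple" otherwise a false alarm.

Sensitivity is ``d' = z(hit rate) - z(false-alarm rate)``; ``d'`` is left
undefined (NaN, not an exception) whenever either rate is exactly 0 or 1.
Percentile bootstrap confidence intervals are formed by resampling a
subject's trials with replacement (stratified within signal/noise class);
a subject counts as chance-consistent when the 95% interval contains 0,
and as "aware" only when *both* tests exclude 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DPrimeResult",
    "rates_from_responses",
    "d_prime",
    "bootstrap_dprime_ci",
    "assess_awareness",
]

DETECTION = "detection"
IDENTIFICATION = "identification"


@dataclass
class DPrimeResult:
    d_prime: float  # NaN when undefined
    hit_rate: float
    fa_rate: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_undefined: int  # bootstrap resamples where d' was undefined
    chance_consistent: bool


def _signal_mask(responses: pd.DataFrame, test: str) -> np.ndarray:
    if test == DETECTION:
        return (responses["stimulus"] != "none").to_numpy()
    if test == IDENTIFICATION:
        return (responses["stimulus"] == "apple").to_numpy()
    raise ValueError(f"unknown test {test!r}")


def _positive_mask(responses: pd.DataFrame, test: str) -> np.ndarray:
    if test == DETECTION:
        return (responses["response"] == "yes").to_numpy()
    return (responses["response"] == "apple").to_numpy()


def rates_from_responses(responses: pd.DataFrame, test: str):
    """(hit_rate, false_alarm_rate) under the test-specific definitions."""
    signal = _signal_mask(responses, test)
    positive = _positive_mask(responses, test)
    if signal.sum() == 0 or (~signal).sum() == 0:
        raise ValueError("need at least one signal and one noise trial")
    hit = float(positive[signal].mean())
    fa = float(positive[~signal].mean())
    return hit, fa


def d_prime(hit_rate: float, fa_rate: float, loglinear: bool = False, n_signal=None, n_noise=None) -> float:
    """``z(hit) - z(fa)``; NaN at extreme rates unless corrected.

    With ``loglinear=True`` (and trial counts supplied) the rates are
    shrunk as ``(count + 0.5) / (n + 1)`` before the quantile transform, so
    extreme rates stay defined.
    """
    for r in (hit_rate, fa_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate {r} outside [0, 1]")
    if loglinear:
        if n_signal is None or n_noise is None:
            raise ValueError("log-linear correction needs trial counts")
        hit_rate = (hit_rate * n_signal + 0.5) / (n_signal + 1)
        fa_rate = (fa_rate * n_noise + 0.5) / (n_noise + 1)
    if hit_rate in (0.0, 1.0) or fa_rate in (0.0, 1.0):
        return float("nan")
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def bootstrap_dprime_ci(
    responses: pd.DataFrame,
    test: str,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> DPrimeResult:
    """Percentile bootstrap interval for a subject's d'.

    Trials are resampled with replacement within the signal and noise
    classes; resamples with an extreme rate yield undefined d' and are
    excluded from the percentiles (their count is reported).  When every
    resample is undefined the interval is NaN.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    signal = _signal_mask(responses, test)
    positive = _positive_mask(responses, test)
    n_sig = int(signal.sum())
    n_noise = int((~signal).sum())
    if n_sig == 0 or n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")
    hit = float(positive[signal].mean())
    fa = float(positive[~signal].mean())
    dp = d_prime(hit, fa)

    rng = np.random.default_rng(seed)
    # resampling iid trials within class: hit counts are binomial draws
    hits = rng.binomial(n_sig, hit, size=n_boot) / n_sig
    fas = rng.binomial(n_noise, fa, size=n_boot) / n_noise
    defined = (hits > 0) & (hits < 1) & (fas > 0) & (fas < 1)
    n_undef = int(n_boot - defined.sum())
    if defined.sum() == 0:
        lo = hi = float("nan")
    else:
        boot = norm.ppf(hits[defined]) - norm.ppf(fas[defined])
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    chance = bool(np.isnan(lo) or (lo <= 0.0 <= hi))
    return DPrimeResult(
        d_prime=dp,
        hit_rate=hit,
        fa_rate=fa,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        n_undefined=n_undef,
        chance_consistent=chance,
    )


def assess_awareness(test1: DPrimeResult, test2: DPrimeResult) -> dict:
    """Per-test chance flags and their conjunction.

    A subject is flagged "aware" only when *both* tests are inconsistent
    with chance (both 95% intervals exclude 0).
    """
    above1 = not test1.chance_consistent
    above2 = not test2.chance_consistent
    return {
        "test1_above_chance": above1,
        "test2_above_chance": above2,
        "aware": above1 and above2,
    }
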