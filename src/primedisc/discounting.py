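"""Hyperbolic temporal discounting with a prime-conditional premium.

The behavioural model: the subjective value of a delayed reward of ``R``
dollars received after ``D`` days is ``SV = R / (1 + k D)`` with per-day
discount rate ``k >= 0``.  On trials preceded by the rewarding brand prime
("apple" trials) the effective discount rate is shifted by an additive
premium ``a``, giving ``SV* = R / (1 + (k + a I_A) D)`` where ``I_A`` is the
apple-condition dummy.  Choices between the delayed option and an immediate
$20 are logistic in the value difference with sensitivity ``omega``
(inverse choice noise): ``P(later) = 1 / (1 + exp(-omega (SV* - 20)))``.

Derived trial-level quantities:

* premium  ``Pi = SV* - SV`` (dollars; zero off apple trials),
* interaction ``Sigma = a * SV*`` (the prime-by-value interaction regressor),
* value distance ``Delta = SV - 20``,
* difficulty ``Gamma = 1 - |2 P(Delta) - 1| = 2 min(P, 1 - P)``, bounded in
  [0, 1], maximal at indifference (``Delta = 0``) and decreasing in
  ``|Delta|``.  A trial is "hard" when its ``Gamma`` exceeds the
  participant's median ``Gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

PRIME_APPLE = "apple"
PRIME_CUP = "cup"
PRIME_CONTROL = "control"

#: immediate option, dollars ("$20 today")
IMMEDIATE_AMOUNT = 20.0

__all__ = [
    "DiscountParams",
    "IMMEDIATE_AMOUNT",
    "PRIME_APPLE",
    "PRIME_CUP",
    "PRIME_CONTROL",
    "subjective_value",
    "primed_subjective_value",
    "choice_probability",
    "priming_premium",
    "priming_interaction",
    "difficulty_index",
    "label_difficulty",
    "indifference_amount",
    "derive_trial_variables",
]


@dataclass(frozen=True)
class DiscountParams:
    """Per-subject behavioural parameters.

    Parameters
    ----------
    k : float
        Discount rate, 1/day, ``k >= 0``.
    a : float
        Premium on the discount rate in the apple condition, 1/day.  May be
        negative, but the primed rate ``k + a`` must stay non-negative.
    omega : float
        Choice sensitivity (logistic slope on the value difference), 1/$,
        strictly positive.
    """

    k: float
    omega: float
    a: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.k) or self.k < 0:
            raise ValueError(f"discount rate k must be >= 0, got {self.k}")
        if not np.isfinite(self.omega) or self.omega <= 0:
            raise ValueError(f"sensitivity omega must be > 0, got {self.omega}")
        if not np.isfinite(self.a) or self.k + self.a < 0:
            raise ValueError(
                f"primed discount rate k + a must be >= 0, got {self.k + self.a}"
            )

    def with_a(self, a: float) -> "DiscountParams":
        return replace(self, a=a)


def _check_nonnegative(name, value):
    value = np.asarray(value, dtype=float)
    if np.any(value < 0) or np.any(~np.isfinite(value)):
        raise ValueError(f"{name} must be finite and non-negative")
    return value


def subjective_value(amount, delay, k):
    """Hyperbolic present value ``amount / (1 + k * delay)``.

    ``amount`` in dollars (> 0), ``delay`` in days (>= 0), ``k`` per day
    (>= 0).  Vectorised over any argument.
    """
    amount = np.asarray(amount, dtype=float)
    if np.any(amount <= 0) or np.any(~np.isfinite(amount)):
        raise ValueError("amount must be finite and positive")
    delay = _check_nonnegative("delay", delay)
    k = _check_nonnegative("k", k)
    out = amount / (1.0 + k * delay)
    return out if out.ndim else float(out)


def primed_subjective_value(amount, delay, params: DiscountParams, is_apple):
    """Present value under the prime-shifted rate ``k + a * I_A``.

    Equals :func:`subjective_value` when ``is_apple`` is false or ``a`` is 0.
    """
    is_apple = np.asarray(is_apple, dtype=bool)
    rate = params.k + params.a * is_apple
    if np.any(rate < 0):
        raise ValueError("effective discount rate k + a*I_A must be >= 0")
    return subjective_value(amount, delay, rate)


def choice_probability(sv_delayed, omega, immediate: float = IMMEDIATE_AMOUNT):
    """Probability of choosing the delayed option.

    ``P = logistic(omega * (SV_delayed - immediate))``, strictly increasing
    in the delayed option's subjective value.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    out = expit(omega * (np.asarray(sv_delayed, dtype=float) - immediate))
    return out if out.ndim else float(out)


def indifference_amount(delay, k, immediate: float = IMMEDIATE_AMOUNT):
    """Delayed amount at which the subject is indifferent, ``20 (1 + k D)``.

    Inverts the hyperbolic valuation at ``SV = immediate``; at this amount
    ``P(later) = 0.5`` exactly, for any sensitivity.
    """
    delay = _check_nonnegative("delay", delay)
    k = _check_nonnegative("k", k)
    out = immediate * (1.0 + k * delay)
    return out if np.asarray(out).ndim else float(out)


def _require_td(prime) -> None:
    if np.any(np.asarray(prime) == PRIME_CONTROL):
        raise ValueError(
            "value-based quantities are undefined on perceptual-control trials"
        )


def priming_premium(prime, amount, delay, params: DiscountParams):
    """Trial premium ``Pi = SV* - SV`` in dollars.

    Exactly zero on cup trials; for ``a > 0`` and positive delay it is
    negative on apple trials (the prime devalues the delayed option).
    """
    _require_td(prime)
    is_apple = np.asarray(prime) == PRIME_APPLE
    sv = subjective_value(amount, delay, params.k)
    sv_star = primed_subjective_value(amount, delay, params, is_apple)
    out = sv_star - sv
    return out if np.asarray(out).ndim else float(out)


def priming_interaction(
    prime, amount, delay, params: DiscountParams, zero_on_cup: bool = False
):
    """Prime-by-value interaction ``Sigma = a * SV*``.

    Evaluated as written on every discounting trial (on cup trials
    ``SV* = SV``); set ``zero_on_cup`` to zero it outside the apple
    condition instead.
    """
    _require_td(prime)
    is_apple = np.asarray(prime) == PRIME_APPLE
    sv_star = primed_subjective_value(amount, delay, params, is_apple)
    out = params.a * sv_star
    if zero_on_cup:
        out = np.where(is_apple, out, 0.0)
    return out if np.asarray(out).ndim else float(out)


def difficulty_index(
    prime, amount, delay, params: DiscountParams, immediate: float = IMMEDIATE_AMOUNT
):
    """Difficulty ``Gamma = 1 - |2 P(Delta) - 1|`` with ``Delta = SV - 20``.

    ``Gamma`` lies in [0, 1], equals 1 at indifference and vanishes as the
    choice becomes trivial; both the fitted ``k`` (through ``Delta``) and
    ``omega`` (through the choice curve) enter.
    """
    _require_td(prime)
    sv = subjective_value(amount, delay, params.k)
    p = choice_probability(sv, params.omega, immediate)
    out = 1.0 - np.abs(2.0 * np.asarray(p) - 1.0)
    return out if np.asarray(out).ndim else float(out)


def label_difficulty(events: pd.DataFrame, params: DiscountParams) -> pd.Series:
    """Median-split hard/easy labels over a participant's discounting trials.

    A trial is hard iff its ``Gamma`` strictly exceeds the median ``Gamma``
    of that participant's discounting trials (ties at the median are easy).
    Control trials get ``NA``.  Returns a nullable boolean Series aligned
    with ``events``.
    """
    if len(events) == 0:
        raise ValueError("empty events table")
    td = events["prime"] != PRIME_CONTROL
    if td.sum() < 2:
        raise ValueError("need at least two discounting trials for a median split")
    gamma = difficulty_index(
        events.loc[td, "prime"].to_numpy(),
        events.loc[td, "amount"].to_numpy(),
        events.loc[td, "delay"].to_numpy(),
        params,
    )
    hard = pd.Series(pd.NA, index=events.index, dtype="boolean")
    hard.loc[td] = gamma > np.median(gamma)
    return hard


def derive_trial_variables(
    events: pd.DataFrame, params: DiscountParams
) -> pd.DataFrame:
    """Attach model-derived columns (sv, sv_star, pi, sigma, delta, gamma, hard).

    Control trials carry NaN in every derived column.  The input table needs
    ``prime``, ``amount`` and ``delay`` columns.
    """
    out = events.copy()
    td = (out["prime"] != PRIME_CONTROL).to_numpy()
    prime = out.loc[td, "prime"].to_numpy()
    amount = out.loc[td, "amount"].to_numpy(dtype=float)
    delay = out.loc[td, "delay"].to_numpy(dtype=float)
    is_apple = prime == PRIME_APPLE

    sv = subjective_value(amount, delay, params.k)
    sv_star = primed_subjective_value(amount, delay, params, is_apple)
    for name in ("sv", "sv_star", "premium_pi", "interaction_sigma", "delta", "gamma"):
        out[name] = np.nan
    out.loc[td, "sv"] = sv
    out.loc[td, "sv_star"] = sv_star
    out.loc[td, "premium_pi"] = sv_star - sv
    out.loc[td, "interaction_sigma"] = params.a * sv_star
    out.loc[td, "delta"] = sv - IMMEDIATE_AMOUNT
    p = choice_probability(sv, params.omega)
    out.loc[td, "gamma"] = 1.0 - np.abs(2.0 * p - 1.0)
    out["hard"] = label_difficulty(out, params)
    return out
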