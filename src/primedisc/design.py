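"""Experimental schedule generation for the discounting-under-priming task.

A session crosses 6 delays x 6 delayed amounts x 2 primes (apple / cup),
each cell repeated 3 times, giving 216 temporal-discounting (TD) trials,
interleaved with 108 perceptual-control (PC) trials, packed into 6 runs of
54 trials.  Every trial occupies a fixed 7000 ms slot:

    fixation 2417 -> pre-mask 84 -> blank 16 -> prime (or blank) 16
    -> blank 16 -> post-mask 400 -> response screen 4000

which sums to 6949 ms; the remaining 51 ms is terminal fixation padding.
Delayed amounts are calibrated per delay so that the model-expected
fraction of "later" choices is one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit

from .discounting import (
    IMMEDIATE_AMOUNT,
    PRIME_APPLE,
    PRIME_CONTROL,
    PRIME_CUP,
    indifference_amount,
)

#: in-trial component durations, ms, in presentation order
TRIAL_COMPONENTS_MS = (
    ("fixation", 2417),
    ("pre_mask", 84),
    ("blank_1", 16),
    ("prime", 16),
    ("blank_2", 16),
    ("post_mask", 400),
    ("response", 4000),
)

#: offset of the visual (mask) onset within a trial, ms — the anchor used by
#: the haemodynamic models (mask + prime + mask + response = 4532 ms,
#: modelled as 4500 ms)
STIM_ONSET_MS = 2417
STIM_DURATION_MS = 4500

#: printed amount envelope, dollars
AMOUNT_ENVELOPE = (20.10, 385.16)


@dataclass(frozen=True)
class DesignConfig:
    """Session layout; defaults reproduce the published trial structure."""

    delays: tuple = (1, 10, 21, 55, 90, 180)
    amounts_per_delay: int = 6
    repetitions: int = 3
    primes: tuple = (PRIME_APPLE, PRIME_CUP)
    n_runs: int = 6
    trials_per_run: int = 54
    trial_duration_ms: int = 7000
    n_pc_trials: int = 108
    response_window_ms: int = 4000
    amount_envelope: tuple = AMOUNT_ENVELOPE
    omega_ref: float = 0.3
    seed: int = 0

    @property
    def n_td_trials(self) -> int:
        return (
            len(self.delays)
            * self.amounts_per_delay
            * self.repetitions
            * len(self.primes)
        )

    def validate(self) -> None:
        total = self.n_td_trials + self.n_pc_trials
        if total != self.n_runs * self.trials_per_run:
            raise ValueError(
                f"{self.n_td_trials} TD + {self.n_pc_trials} PC trials do not "
                f"pack into {self.n_runs} runs of {self.trials_per_run}"
            )
        if self.n_td_trials % self.n_runs or self.n_pc_trials % self.n_runs:
            raise ValueError("TD and PC counts must divide evenly across runs")
        comp = sum(d for _, d in TRIAL_COMPONENTS_MS)
        if comp > self.trial_duration_ms:
            raise ValueError(
                f"trial components ({comp} ms) exceed the "
                f"{self.trial_duration_ms} ms trial slot"
            )


def calibrate_amounts(
    k_pretest: float,
    delays=(1, 10, 21, 55, 90, 180),
    n_amounts: int = 6,
    omega_ref: float = 0.3,
    envelope: tuple = AMOUNT_ENVELOPE,
    immediate: float = IMMEDIATE_AMOUNT,
) -> dict:
    """Per-delay amount grids centred on the pre-test indifference point.

    For each delay the ``n_amounts`` values hit later-choice probabilities
    evenly spaced and symmetric about one half (octiles 0.125 .. 0.875 for
    six amounts) under the reference sensitivity ``omega_ref``, so the
    expected later-choice fraction over the grid is 0.5 by construction.
    Amounts are clipped to the dollar envelope and rounded to cents.
    """
    if k_pretest <= 0:
        raise ValueError("k_pretest must be > 0")
    targets = np.linspace(0.125, 0.875, n_amounts)
    out = {}
    for d in delays:
        sv = immediate + logit(targets) / omega_ref
        amounts = sv * (1.0 + k_pretest * d)
        amounts = np.clip(amounts, *envelope)
        if np.any(amounts <= 0):
            raise ValueError(f"calibrated amounts non-positive at delay {d}")
        amounts = np.round(amounts, 2)
        # the envelope floor can collapse neighbouring grid points at short
        # delays; keep the six amounts distinct by cent spacing
        for i in range(1, n_amounts):
            if amounts[i] <= amounts[i - 1]:
                amounts[i] = amounts[i - 1] + 0.01
        out[d] = amounts
    return out


def _assign_cells_to_runs(n_cells: int, repetitions: int, n_runs: int, rng):
    """Give each cell `repetitions` distinct runs with exact per-run balance.

    Cells are randomly permuted, then cell j is sent to runs
    {j, j+1, .., j+reps-1} mod n_runs — every run receives the same number
    of cells and no cell repeats within a run.
    """
    if repetitions > n_runs:
        raise ValueError("repetitions cannot exceed the number of runs")
    if (n_cells * repetitions) % n_runs:
        raise ValueError("cell repetitions do not divide evenly across runs")
    order = rng.permutation(n_cells)
    runs = np.empty((n_cells, repetitions), dtype=int)
    for slot, cell in enumerate(order):
        runs[cell] = (slot + np.arange(repetitions)) % n_runs
    return runs


def build_design(config: DesignConfig, k_pretest: float) -> pd.DataFrame:
    """Full session events table.

    Columns: ``run`` (1-based), ``trial`` (within run), ``onset_s`` (trial
    start within run), ``stim_onset_s`` (visual onset used by the GLMs),
    ``duration_s``, ``trial_type`` (TD/PC), ``prime``, ``amount``, ``delay``,
    ``side_later`` (TD) / ``side_red`` (PC reused column), ``cell``.

    Balance guarantees: each (delay, amount, prime) cell appears exactly
    ``repetitions`` times per session and at most once per run; per-run
    prime counts are equal; option sides are counterbalanced 50/50 per run.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grids = calibrate_amounts(
        k_pretest,
        config.delays,
        config.amounts_per_delay,
        config.omega_ref,
        config.amount_envelope,
    )

    # one run-assignment per prime so per-run prime counts are exactly equal
    cells = [
        (d, ai)
        for d in config.delays
        for ai in range(config.amounts_per_delay)
    ]
    rows = []
    for prime in config.primes:
        assignment = _assign_cells_to_runs(
            len(cells), config.repetitions, config.n_runs, rng
        )
        for ci, (d, ai) in enumerate(cells):
            for run in assignment[ci]:
                rows.append(
                    dict(
                        run=int(run) + 1,
                        trial_type="TD",
                        prime=prime,
                        amount=float(grids[d][ai]),
                        delay=float(d),
                        cell=f"{prime}:{d}:{ai}",
                    )
                )
    pc_per_run = config.n_pc_trials // config.n_runs
    for run in range(1, config.n_runs + 1):
        for _ in range(pc_per_run):
            rows.append(
                dict(
                    run=run,
                    trial_type="PC",
                    prime=PRIME_CONTROL,
                    amount=np.nan,
                    delay=np.nan,
                    cell="pc",
                )
            )
    events = pd.DataFrame(rows)

    # shuffle within run, counterbalance sides 50/50 within run and type
    parts = []
    for run, grp in events.groupby("run", sort=True):
        grp = grp.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(
            drop=True
        )
        side = np.empty(len(grp), dtype=object)
        for ttype in ("TD", "PC"):
            idx = np.flatnonzero((grp["trial_type"] == ttype).to_numpy())
            half = len(idx) // 2
            sides = np.array(["left"] * half + ["right"] * (len(idx) - half))
            side[idx] = rng.permutation(sides)
        grp["side_later"] = side
        grp["trial"] = np.arange(1, len(grp) + 1)
        grp["onset_s"] = (grp["trial"] - 1) * (config.trial_duration_ms / 1000.0)
        parts.append(grp)
    events = pd.concat(parts, ignore_index=True)
    events["stim_onset_s"] = events["onset_s"] + STIM_ONSET_MS / 1000.0
    events["duration_s"] = STIM_DURATION_MS / 1000.0
    cols = [
        "run",
        "trial",
        "onset_s",
        "stim_onset_s",
        "duration_s",
        "trial_type",
        "prime",
        "amount",
        "delay",
        "side_later",
        "cell",
    ]
    return events[cols]


def schedule_timing(events: pd.DataFrame, config: DesignConfig) -> pd.DataFrame:
    """Expand each trial into its component timeline (long format).

    Returns one row per (trial, component) with absolute within-run onset
    and duration in ms; each trial's components plus terminal padding sum
    exactly to the trial slot.  PC trials show a blank in the prime slot.
    """
    comp_ms = sum(d for _, d in TRIAL_COMPONENTS_MS)
    pad = config.trial_duration_ms - comp_ms
    if pad < 0:
        raise ValueError("trial components exceed trial duration")
    rows = []
    for _, tr in events.iterrows():
        t = tr["onset_s"] * 1000.0
        for name, dur in TRIAL_COMPONENTS_MS:
            shown = name
            if name == "prime" and tr["trial_type"] == "PC":
                shown = "blank_prime_slot"
            rows.append(
                dict(
                    run=tr["run"],
                    trial=tr["trial"],
                    component=shown,
                    onset_ms=t,
                    duration_ms=dur,
                )
            )
            t += dur
        rows.append(
            dict(
                run=tr["run"],
                trial=tr["trial"],
                component="padding",
                onset_ms=t,
                duration_ms=pad,
            )
        )
    return pd.DataFrame(rows)


def run_stimulus_seconds(config: DesignConfig) -> float:
    """Scheduled stimulus time per run (378 s at defaults)."""
    return config.trials_per_run * config.trial_duration_ms / 1000.0
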