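"""Synthetic participants, choices, visibility responses and BOLD volumes.

The generator emulates the study conditions end to end: 13 participants
whose (k, a, omega) are drawn from truncated normal populations matching
the reported group moments (k: 0.024 +/- 0.018, a: 0.06 +/- 0.31), 216
discounting plus 108 perceptual-control trials over 6 runs, binary choices
from the logistic-hyperbolic model with the prime premium, equal-variance
Gaussian-observer visibility responses, and 4-D BOLD series (TR 2 s, 189
volumes per run) with planted effects, AR(1) noise and slow cosine drift.

Planted effects come in two families:

* parametric — a region's evoked amplitude scales trial-by-trial with a
  standardised model variable (SV, the interaction Sigma, or the premium
  Pi on apple trials);
* pattern — each class of a dichotomy (apple/cup, now/later, easy/hard)
  adds a subject-specific spatial pattern that sums to zero over the
  region's voxels, with the two classes carrying opposite signs.  Group
  univariate contrasts are null in expectation (patterns are idiosyncratic
  across subjects and spatially mean-free) while a within-subject
  multivariate decoder can read the class from the pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .bold import VolumeSeries, cosine_drift_basis, ellipsoid_mask, event_regressor, hrf_kernel
from .design import DesignConfig, build_design
from .discounting import (
    IMMEDIATE_AMOUNT,
    PRIME_APPLE,
    PRIME_CONTROL,
    DiscountParams,
    derive_trial_variables,
)

__all__ = [
    "PopulationSpec",
    "BoldSpec",
    "PlantedRegion",
    "sample_participants",
    "simulate_choices",
    "simulate_visibility",
    "simulate_bold",
    "default_regions",
    "simulate_subject",
]

PARAMETRIC_EFFECTS = ("sv_parametric", "interaction_parametric", "premium_parametric")
PATTERN_EFFECTS = ("prime_pattern", "outcome_pattern", "difficulty_pattern")


@dataclass(frozen=True)
class PopulationSpec:
    """Population moments for participant sampling (truncated normals)."""

    n_subjects: int = 13
    k_mean: float = 0.024
    k_sd: float = 0.018
    a_mean: float = 0.06
    a_sd: float = 0.31
    omega_mean: float = 0.3
    omega_sd: float = 0.1
    seed: int = 0


@dataclass(frozen=True)
class PlantedRegion:
    """A cuboid region with a ground-truth effect.

    ``corner`` is the lower voxel corner, ``shape`` the cuboid extent;
    ``effect`` one of the parametric or pattern effect names; ``amplitude``
    the effect size in signal units (per unit standardised modulator for
    parametric effects; pattern standard deviation for pattern effects).
    """

    corner: tuple
    shape: tuple
    effect: str
    amplitude: float = 1.0

    def mask(self, grid) -> np.ndarray:
        for c, s, g in zip(self.corner, self.shape, grid):
            if c < 0 or c + s > g:
                raise ValueError(f"region {self.corner}+{self.shape} outside {grid}")
        m = np.zeros(grid, dtype=bool)
        sl = tuple(slice(c, c + s) for c, s in zip(self.corner, self.shape))
        m[sl] = True
        return m


@dataclass(frozen=True)
class BoldSpec:
    """Synthetic acquisition geometry, noise model and planted regions."""

    grid: tuple = (24, 24, 18)
    voxel_size_mm: float = 4.0
    tr_ms: float = 2000.0
    volumes_per_run: int = 189
    n_runs: int = 6
    baseline: float = 100.0
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 1.0
    task_amplitude: float = 0.8  # evoked response of every trial, in-mask
    regions: tuple = ()

    def validate(self, run_stim_s: float) -> None:
        if self.volumes_per_run * self.tr_ms / 1000.0 < run_stim_s:
            raise ValueError("run too short for the scheduled stimulus time")
        masks = [r.mask(self.grid) for r in self.regions]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if np.any(masks[i] & masks[j]):
                    raise ValueError("planted regions must be disjoint")


def default_regions(amplitude: float = 1.0) -> tuple:
    """A disjoint set of planted regions used by the worked examples."""
    return (
        PlantedRegion((3, 3, 3), (4, 4, 4), "sv_parametric", amplitude),
        PlantedRegion((15, 3, 3), (4, 4, 4), "interaction_parametric", amplitude),
        PlantedRegion((3, 15, 3), (4, 4, 4), "premium_parametric", amplitude),
        PlantedRegion((9, 9, 7), (4, 4, 4), "prime_pattern", amplitude),
        PlantedRegion((15, 15, 10), (4, 4, 4), "outcome_pattern", amplitude),
        PlantedRegion((3, 3, 10), (4, 4, 4), "difficulty_pattern", amplitude),
    )


def sample_participants(spec: PopulationSpec) -> list:
    """Draw per-subject DiscountParams honoring the sign constraints.

    Rejection sampling from normals truncated to k > 0, k + a > 0,
    omega > 0.  Zero standard deviations reproduce the means exactly
    (raising if the means themselves violate the constraints).
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    max_tries = 100_000
    for _ in range(spec.n_subjects):
        for attempt in range(max_tries):
            k = spec.k_mean + spec.k_sd * rng.standard_normal()
            a = spec.a_mean + spec.a_sd * rng.standard_normal()
            omega = spec.omega_mean + spec.omega_sd * rng.standard_normal()
            if k > 0 and k + a > 0 and omega > 0:
                out.append(DiscountParams(k=k, a=a, omega=omega))
                break
            if spec.k_sd == spec.a_sd == spec.omega_sd == 0:
                raise ValueError("population means violate the sign constraints")
        else:
            raise ValueError("truncation region too small: rejection sampling failed")
    return out


def simulate_choices(
    params: DiscountParams,
    schedule: pd.DataFrame,
    seed: int = 0,
    pc_correct_prob: float = 0.98,
    miss_prob: float = 0.0,
) -> pd.DataFrame:
    """Draw now/later choices from the generative priming model.

    Each discounting trial is Bernoulli with
    ``P(later) = logistic(omega (SV* - 20))``; perceptual-control trials
    are answered correctly with probability ``pc_correct_prob`` (nuisance).
    ``miss_prob`` marks trials as missed (``choice = 'none'``).
    """
    rng = np.random.default_rng(seed)
    ev = derive_trial_variables(schedule, params)
    td = ev["prime"] != PRIME_CONTROL
    p_later = expit(params.omega * (ev.loc[td, "sv_star"] - IMMEDIATE_AMOUNT))
    choice = np.where(rng.random(td.sum()) < p_later, "later", "now")
    ev["choice"] = "none"
    ev.loc[td, "choice"] = choice
    pc = ~td
    pc_resp = np.where(
        rng.random(pc.sum()) < pc_correct_prob, "correct", "incorrect"
    )
    ev.loc[pc, "choice"] = pc_resp
    if miss_prob > 0:
        missed = rng.random(len(ev)) < miss_prob
        ev.loc[missed, "choice"] = "none"
    return ev


def simulate_visibility(
    d_prime_true: float,
    n_trials: int,
    test: str = "detection",
    seed: int = 0,
) -> pd.DataFrame:
    """Equal-variance Gaussian observer with an unbiased criterion.

    Detection: half the trials carry a masked image (half apple, half cup),
    the observer answers yes when the evidence exceeds d'/2.  Identification:
    one of four images per trial; the apple response is emitted when the
    apple-evidence channel exceeds the criterion, otherwise one of the
    remaining images is picked at random.
    """
    if n_trials % 2:
        raise ValueError("n_trials must be even")
    rng = np.random.default_rng(seed)
    c = d_prime_true / 2.0
    if test == "detection":
        half = n_trials // 2
        stim = np.array(
            ["apple"] * (half - half // 2) + ["cup"] * (half // 2) + ["none"] * half
        )
        rng.shuffle(stim)
        signal = stim != "none"
        evidence = rng.standard_normal(n_trials) + d_prime_true * signal
        resp = np.where(evidence > c, "yes", "no")
    elif test == "identification":
        others = ["cup", "other_logo", "other_object"]
        stim = np.array((["apple"] + others) * (n_trials // 4 + 1))[:n_trials]
        rng.shuffle(stim)
        signal = stim == "apple"
        evidence = rng.standard_normal(n_trials) + d_prime_true * signal
        resp = np.where(
            evidence > c, "apple", rng.choice(others, size=n_trials)
        )
    else:
        raise ValueError(f"unknown test {test!r}")
    return pd.DataFrame(
        {"trial": np.arange(1, n_trials + 1), "stimulus": stim, "response": resp}
    )


def _pattern_labels(ev: pd.DataFrame, effect: str) -> np.ndarray:
    """Signed class labels (+1/-1/0) per trial for a pattern effect."""
    s = np.zeros(len(ev))
    td = (ev["prime"] != PRIME_CONTROL).to_numpy()
    if effect == "prime_pattern":
        s[(ev["prime"] == PRIME_APPLE).to_numpy()] = 1.0
        s[(ev["prime"] == "cup").to_numpy()] = -1.0
    elif effect == "outcome_pattern":
        s[(ev["choice"] == "later").to_numpy() & td] = 1.0
        s[(ev["choice"] == "now").to_numpy() & td] = -1.0
    elif effect == "difficulty_pattern":
        hard = ev["hard"].to_numpy(dtype=object)
        s[[h is True for h in hard]] = 1.0
        s[[h is False for h in hard]] = -1.0
    else:
        raise ValueError(effect)
    return s


def _parametric_amplitudes(ev: pd.DataFrame, effect: str) -> np.ndarray:
    """Standardised modulator per trial (zero off the relevant trials)."""
    td = (ev["prime"] != PRIME_CONTROL).to_numpy()
    amp = np.zeros(len(ev))
    if effect == "sv_parametric":
        x = ev.loc[td, "sv"].to_numpy(dtype=float)
        sel = td
    elif effect == "interaction_parametric":
        x = ev.loc[td, "interaction_sigma"].to_numpy(dtype=float)
        sel = td
    elif effect == "premium_parametric":
        apple = (ev["prime"] == PRIME_APPLE).to_numpy()
        x = ev.loc[apple, "premium_pi"].to_numpy(dtype=float)
        sel = apple
    else:
        raise ValueError(effect)
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    amp[sel] = z
    return amp


def simulate_bold(
    schedule: pd.DataFrame,
    params: DiscountParams,
    dataset: pd.DataFrame,
    spec: BoldSpec,
    seed: int = 0,
):
    """Forward-model a subject's 4-D BOLD series.

    Returns ``(VolumeSeries, ground_truth)`` where ``ground_truth`` maps
    region names (``effect:index``) to boolean masks.  Voxel time series
    are the sum of baseline, HRF-convolved trial responses (every in-mask
    voxel responds to every trial with ``task_amplitude``; planted regions
    add their parametric or pattern term), cosine drift with random
    coefficients and AR(1) Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    ev = derive_trial_variables(dataset, params)
    spec.validate(schedule["onset_s"].max() + 7.0)
    mask = ellipsoid_mask(spec.grid)
    n_vox = int(mask.sum())
    tr_s = spec.tr_ms / 1000.0
    T = spec.volumes_per_run
    kernel = hrf_kernel(spec.tr_ms)

    # voxel indices of each region within the flat masked array
    flat_index = np.full(spec.grid, -1, dtype=int)
    flat_index[mask] = np.arange(n_vox)
    ground_truth = {}
    region_vox = []
    patterns = []
    for i, reg in enumerate(spec.regions):
        rmask = reg.mask(spec.grid) & mask
        ground_truth[f"{reg.effect}:{i}"] = rmask
        vox = flat_index[rmask]
        region_vox.append(vox)
        if reg.effect in PATTERN_EFFECTS:
            w = rng.standard_normal(len(vox))
            w -= w.mean()  # spatially mean-free pattern
            sd = w.std()
            patterns.append(reg.amplitude * w / sd if sd > 0 else w)
        else:
            patterns.append(None)

    data = np.empty(spec.grid + (spec.n_runs * T,))
    data[:] = np.nan
    runs = sorted(schedule["run"].unique())
    if len(runs) != spec.n_runs:
        raise ValueError("schedule runs do not match the BOLD spec")
    # per-trial response: a 4.5 s boxcar passed through the double-gamma
    # kernel, sampled at volume resolution and supported on the 12 s
    # post-onset window, placed at the volume containing the visual onset.
    # Generating at volume resolution keeps the evoked signal inside the
    # span of a volume-locked deconvolution basis (real BOLD adds sub-TR
    # latency jitter and longer undershoots; see the methods note).
    n_kernel = 6
    trial_kernel = event_regressor(
        [0.0], [4.5], [1.0], n_scans=n_kernel, tr_s=tr_s, kernel=kernel
    )
    for ri, run in enumerate(runs):
        evr = ev.loc[ev["run"] == run].reset_index(drop=True)
        onsets = evr["stim_onset_s"].to_numpy(dtype=float)
        onset_vol = np.floor(onsets / tr_s).astype(int)
        n_tr = len(evr)
        R = np.zeros((T, n_tr))
        for t in range(n_tr):
            idx = onset_vol[t] + np.arange(n_kernel)
            keep = idx < T
            R[idx[keep], t] = trial_kernel[keep]
        # amplitude matrix, n_trials x n_vox
        A = np.full((n_tr, n_vox), spec.task_amplitude)
        for reg, vox, w in zip(spec.regions, region_vox, patterns):
            if reg.effect in PARAMETRIC_EFFECTS:
                amp = _parametric_amplitudes(evr, reg.effect)
                A[:, vox] += reg.amplitude * amp[:, None]
            else:
                s = _pattern_labels(evr, reg.effect)
                A[:, vox] += np.outer(s, w)
        signal = R @ A  # T x n_vox

        drift_basis = cosine_drift_basis(T, tr_s, highpass_s=256.0)
        drift = drift_basis @ (
            spec.drift_amplitude
            * rng.standard_normal((drift_basis.shape[1], n_vox))
        )
        if spec.noise_sd > 0:
            eps = rng.standard_normal((T, n_vox)) * spec.noise_sd
            if spec.ar1_rho:
                from scipy.signal import lfilter

                eps = lfilter([1.0], [1.0, -spec.ar1_rho], eps, axis=0)
            noise = eps
        else:
            noise = 0.0
        run_block = np.zeros(spec.grid + (T,))
        run_block[mask] = (spec.baseline + signal + drift + noise).T
        data[..., ri * T : (ri + 1) * T] = run_block

    data[~mask] = 0.0
    vols = VolumeSeries(
        data=data,
        tr_s=tr_s,
        n_runs=spec.n_runs,
        volumes_per_run=T,
        voxel_size_mm=spec.voxel_size_mm,
        mask=mask,
    )
    return vols, ground_truth


def simulate_subject(
    params: DiscountParams,
    config: DesignConfig | None = None,
    bold_spec: BoldSpec | None = None,
    seed: int = 0,
    k_pretest: float | None = None,
    with_bold: bool = False,
):
    """Convenience wrapper: schedule + choices (+ BOLD) for one subject."""
    config = config or DesignConfig(seed=seed)
    if config.seed != seed:
        config = replace(config, seed=seed)
    schedule = build_design(config, k_pretest if k_pretest is not None else params.k)
    dataset = simulate_choices(params, schedule, seed=seed + 1)
    if not with_bold:
        return schedule, dataset
    bold_spec = bold_spec or BoldSpec()
    vols, truth = simulate_bold(schedule, params, dataset, bold_spec, seed=seed + 2)
    return schedule, dataset, vols, truth
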