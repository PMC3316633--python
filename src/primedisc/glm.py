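"""Univariate parametric GLMs and cluster-level permutation inference.

Two subject-level models of the discounting runs, mirroring the two
behavioural priming models:

* interaction model — apple/cup/control condition boxcars; all TD trials
  carry a mean-centred subjective-value (SV) modulator, followed by the
  prime-by-value interaction (Sigma) modulator serially orthogonalised
  against SV.  Reversing the modulator order attributes the shared
  variance to the interaction instead.
* premium model — the SV modulator is included as a regressor of no
  interest on all TD trials; the premium (Pi) modulator enters on apple
  trials only, orthogonalised against SV.  Optionally only trials whose
  choice the fitted model predicts correctly are modulated.

Trials are modelled from the visual (mask) onset for 4500 ms, convolved
with the canonical double-gamma response; each run carries a 128 s
high-pass discrete-cosine set plus an intercept.  Group inference is a
one-sample test across subject contrast maps with cluster-forming
threshold Z > 1.96 (6-connectivity) and family-wise-error control by
sign-flip max-cluster-size permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .bold import VolumeSeries, cosine_drift_basis, event_regressor, hrf_kernel, smooth_map
from .discounting import (
    PRIME_APPLE,
    PRIME_CONTROL,
    PRIME_CUP,
    DiscountParams,
    derive_trial_variables,
)

__all__ = [
    "RunDesign",
    "FirstLevelFit",
    "Cluster",
    "build_interaction_design",
    "build_premium_design",
    "build_condition_design",
    "fit_glm",
    "group_cluster_fwe",
    "condition_contrast_null",
]

Z_THRESH_DEFAULT = 1.96
SIX_CONN = ndimage.generate_binary_structure(3, 1)


@dataclass
class RunDesign:
    """Design matrix for one run: named columns sampled at frame times."""

    matrix: np.ndarray  # n_scans x n_cols
    columns: list
    run: int

    def col(self, name: str) -> np.ndarray:
        return self.matrix[:, self.columns.index(name)]


@dataclass
class Cluster:
    size: int
    peak_z: float
    peak_ijk: tuple
    p_fwe: float


def _orthogonalize(v: np.ndarray, against: np.ndarray) -> np.ndarray:
    """Residual of v after OLS projection onto the columns of `against`."""
    beta, *_ = np.linalg.lstsq(against, v, rcond=None)
    return v - against @ beta


def _run_events(events: pd.DataFrame, run: int) -> pd.DataFrame:
    return events.loc[events["run"] == run].reset_index(drop=True)


def _base_columns(ev, n_scans, tr_s, kernel):
    """Condition boxcar regressors (apple, cup, control) for one run."""
    cols, names = [], []
    for prime, name in (
        (PRIME_APPLE, "apple"),
        (PRIME_CUP, "cup"),
        (PRIME_CONTROL, "control"),
    ):
        sel = ev["prime"] == prime
        if sel.sum() == 0:
            continue
        reg = event_regressor(
            ev.loc[sel, "stim_onset_s"],
            ev.loc[sel, "duration_s"],
            1.0,
            n_scans,
            tr_s,
            kernel=kernel,
        )
        cols.append(reg)
        names.append(name)
    return cols, names


def _modulated(ev, sel, values, n_scans, tr_s, kernel):
    """Mean-centred parametric modulator regressor over selected trials."""
    amp = np.asarray(values, dtype=float)
    amp = amp - amp.mean()
    return event_regressor(
        ev.loc[sel, "stim_onset_s"],
        ev.loc[sel, "duration_s"],
        amp,
        n_scans,
        tr_s,
        kernel=kernel,
    )


def _assemble(cols, names, n_scans, tr_s, highpass_s, run):
    drift = cosine_drift_basis(n_scans, tr_s, highpass_s)
    mat = np.column_stack(cols + [drift, np.ones(n_scans)])
    names = names + [f"drift_{j}" for j in range(drift.shape[1])] + ["intercept"]
    # degenerate (all-zero) modulators are dropped by the caller; anything
    # left must carry variance
    return RunDesign(matrix=mat, columns=names, run=run)


def build_interaction_design(
    events: pd.DataFrame,
    params: DiscountParams,
    n_scans: int,
    tr_s: float,
    highpass_s: float = 128.0,
    reverse_order: bool = False,
) -> list:
    """Per-run designs for the prime-by-value interaction model.

    Modulators enter in the order [SV, Sigma] (or reversed), each
    orthogonalised against the condition regressors and, serially, against
    the modulators entered before it.  An all-zero Sigma modulator (premium
    a = 0) is dropped.
    """
    derived = derive_trial_variables(events, params)
    kernel = hrf_kernel(tr_s * 1000.0)
    designs = []
    for run in sorted(events["run"].unique()):
        ev = _run_events(derived, run)
        base, names = _base_columns(ev, n_scans, tr_s, kernel)
        td = ev["prime"] != PRIME_CONTROL
        mods = [
            ("sv_mod", _modulated(ev, td, ev.loc[td, "sv"], n_scans, tr_s, kernel)),
            (
                "sigma_mod",
                _modulated(
                    ev, td, ev.loc[td, "interaction_sigma"], n_scans, tr_s, kernel
                ),
            ),
        ]
        if reverse_order:
            mods = mods[::-1]
        cols = list(base)
        mnames = list(names)
        ortho_pool = list(base)
        for name, reg in mods:
            if np.allclose(reg, 0.0):
                continue  # degenerate modulator (e.g. a = 0): dropped
            reg = _orthogonalize(reg, np.column_stack(ortho_pool))
            cols.append(reg)
            mnames.append(name)
            ortho_pool.append(reg)
        designs.append(_assemble(cols, mnames, n_scans, tr_s, highpass_s, run))
    return designs


def build_premium_design(
    events: pd.DataFrame,
    params: DiscountParams,
    n_scans: int,
    tr_s: float,
    highpass_s: float = 128.0,
    correct_only: np.ndarray | None = None,
) -> list:
    """Per-run designs for the apple-specific premium model.

    SV modulates all TD trials (of no interest); the premium Pi modulates
    apple trials only and is orthogonalised against the SV regressor.  With
    ``correct_only`` (a boolean per-trial mask aligned with ``events``) the
    modulated trials are restricted to correctly predicted ones.
    """
    derived = derive_trial_variables(events, params)
    if correct_only is not None:
        derived = derived.loc[np.asarray(correct_only, dtype=bool) |
                              (derived["prime"] == PRIME_CONTROL)]
    kernel = hrf_kernel(tr_s * 1000.0)
    designs = []
    for run in sorted(events["run"].unique()):
        ev = _run_events(derived, run)
        base, names = _base_columns(ev, n_scans, tr_s, kernel)
        td = ev["prime"] != PRIME_CONTROL
        apple = ev["prime"] == PRIME_APPLE
        sv_reg = _modulated(ev, td, ev.loc[td, "sv"], n_scans, tr_s, kernel)
        cols = list(base) + [_orthogonalize(sv_reg, np.column_stack(base))]
        mnames = list(names) + ["sv_mod"]
        pi_reg = _modulated(
            ev, apple, ev.loc[apple, "premium_pi"], n_scans, tr_s, kernel
        )
        if not np.allclose(pi_reg, 0.0):
            pi_reg = _orthogonalize(pi_reg, np.column_stack(cols))
            cols.append(pi_reg)
            mnames.append("pi_mod")
        designs.append(_assemble(cols, mnames, n_scans, tr_s, highpass_s, run))
    return designs


def build_condition_design(
    events: pd.DataFrame,
    n_scans: int,
    tr_s: float,
    highpass_s: float = 128.0,
) -> list:
    """Condition-boxcar-only designs (apple / cup / control), no modulators."""
    kernel = hrf_kernel(tr_s * 1000.0)
    designs = []
    for run in sorted(events["run"].unique()):
        ev = _run_events(events, run)
        cols, names = _base_columns(ev, n_scans, tr_s, kernel)
        designs.append(_assemble(cols, names, n_scans, tr_s, highpass_s, run))
    return designs


@dataclass
class FirstLevelFit:
    """Per-run OLS betas over mask voxels, with contrast helpers."""

    betas: np.ndarray  # n_runs x n_cols x n_voxels
    columns: list
    mask: np.ndarray
    grid: tuple

    def _weights(self, contrast) -> np.ndarray:
        if isinstance(contrast, str):
            w = np.zeros(len(self.columns))
            w[self.columns.index(contrast)] = 1.0
            return w
        if isinstance(contrast, dict):
            w = np.zeros(len(self.columns))
            for name, v in contrast.items():
                w[self.columns.index(name)] = v
            return w
        return np.asarray(contrast, dtype=float)

    def contrast_map(self, contrast) -> np.ndarray:
        """Across-run mean contrast effect as a 3-D map (NaN off-mask)."""
        w = self._weights(contrast)
        eff = np.tensordot(w, self.betas.mean(axis=0), axes=(0, 0))
        return self._to_3d(eff)

    def t_map(self, contrast) -> np.ndarray:
        """Across-run one-sample t of the per-run contrast effects."""
        w = self._weights(contrast)
        per_run = np.tensordot(w, self.betas, axes=(0, 1))  # runs x voxels
        n = per_run.shape[0]
        mean = per_run.mean(axis=0)
        sd = per_run.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        return self._to_3d(t)

    def _to_3d(self, values: np.ndarray) -> np.ndarray:
        out = np.full(self.grid, np.nan)
        out[self.mask] = values
        return out


def fit_glm(volumes: VolumeSeries, designs: list) -> FirstLevelFit:
    """Per-run ordinary least squares over mask voxels.

    Every design must share the run's frame count; a rank-deficient design
    raises an error naming the collinear columns.  Betas for columns absent
    in a run (e.g. a dropped degenerate modulator) are NaN-free: designs
    must share the same column list across runs.
    """
    columns = designs[0].columns
    for d in designs:
        if d.columns != columns:
            raise ValueError("designs must share columns across runs")
        if d.matrix.shape[0] != volumes.volumes_per_run:
            raise ValueError("design frame count does not match the volumes")
        rank = np.linalg.matrix_rank(d.matrix)
        if rank < d.matrix.shape[1]:
            # identify an offending column by leave-one-out rank
            for j, name in enumerate(d.columns):
                sub = np.delete(d.matrix, j, axis=1)
                if np.linalg.matrix_rank(sub) == rank:
                    raise ValueError(
                        f"design for run {d.run} is rank-deficient; "
                        f"column '{name}' is collinear"
                    )
            raise ValueError(f"design for run {d.run} is rank-deficient")
    n_vox = int(volumes.mask.sum())
    betas = np.empty((volumes.n_runs, len(columns), n_vox))
    for r, d in enumerate(designs):
        Y = volumes.run_data(r).T  # time x voxels
        b, *_ = np.linalg.lstsq(d.matrix, Y, rcond=None)
        betas[r] = b
    return FirstLevelFit(
        betas=betas, columns=columns, mask=volumes.mask, grid=volumes.grid
    )


def _one_sample_z(maps: np.ndarray) -> np.ndarray:
    """Voxelwise one-sample t across subjects converted to Z."""
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = stats.t.sf(t, df=n - 1)
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    return stats.norm.isf(p)


def _cluster_sizes(z: np.ndarray, z_thresh: float, mask: np.ndarray):
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = z[mask] > z_thresh
    labels, n = ndimage.label(supra, structure=SIX_CONN)
    if n == 0:
        return labels, np.array([], dtype=int)
    sizes = ndimage.sum_labels(supra, labels, index=np.arange(1, n + 1)).astype(int)
    return labels, sizes


def group_cluster_fwe(
    subject_maps: list,
    mask: np.ndarray,
    z_thresh: float = Z_THRESH_DEFAULT,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> list:
    """Sign-flip max-cluster-size permutation test on one-sample group maps.

    Subject maps are stacked, thresholded at cluster-forming ``z_thresh``
    after a voxelwise one-sample t -> Z transform, and cluster sizes are
    compared with the permutation distribution of the maximum cluster size
    under per-subject sign flips (the exact flip set is enumerated when
    ``2**n_subjects <= n_perm``).  Returns clusters with ``p_fwe < alpha``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    maps = np.stack([np.asarray(m) for m in subject_maps])
    if maps.shape[0] < 5:
        raise ValueError("need at least 5 subject maps")
    n_subj = maps.shape[0]
    flat = maps[:, mask]

    z_obs = np.full(mask.shape, -np.inf)
    z_obs[mask] = _one_sample_z(flat)[...]
    labels, sizes = _cluster_sizes(z_obs, z_thresh, mask)
    signs = [1.0] * len(sizes)
    if two_sided:
        z_neg = np.full(mask.shape, -np.inf)
        z_neg[mask] = -z_obs[mask]
        labels_neg, sizes_neg = _cluster_sizes(z_neg, z_thresh, mask)
        labels_neg = np.where(labels_neg > 0, labels_neg + len(sizes), 0)
        labels = labels + labels_neg
        sizes = np.concatenate([sizes, sizes_neg])
        signs += [-1.0] * len(sizes_neg)

    # permutation null of the max cluster size
    if 2**n_subj <= n_perm:
        flips = np.array(
            [[1 if (i >> s) & 1 else -1 for s in range(n_subj)]
             for i in range(2**n_subj)]
        )
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    null_max = np.empty(len(flips), dtype=int)
    for i, f in enumerate(flips):
        z = np.full(mask.shape, -np.inf)
        z[mask] = _one_sample_z(flat * f[:, None])
        if two_sided:
            zneg = np.full(mask.shape, -np.inf)
            zneg[mask] = -z[mask]
            _, s_pos = _cluster_sizes(z, z_thresh, mask)
            _, s_neg = _cluster_sizes(zneg, z_thresh, mask)
            s = np.concatenate([s_pos, s_neg])
        else:
            _, s = _cluster_sizes(z, z_thresh, mask)
        null_max[i] = s.max() if len(s) else 0

    clusters = []
    for ci, size in enumerate(sizes, start=1):
        p = float((null_max >= size).mean())
        if p < alpha:
            in_cluster = labels == ci
            sign = signs[ci - 1]
            peak_flat = np.nanargmax(np.where(in_cluster, sign * z_obs, -np.inf))
            peak_ijk = np.unravel_index(peak_flat, mask.shape)
            clusters.append(
                Cluster(
                    size=int(size),
                    peak_z=float(z_obs[peak_ijk]),
                    peak_ijk=tuple(int(i) for i in peak_ijk),
                    p_fwe=p,
                )
            )
    return sorted(clusters, key=lambda c: -c.size)


def condition_contrast_null(
    subject_results: list,
    mask: np.ndarray,
    fwhm_mm: float = 8.0,
    voxel_size_mm: float = 4.0,
    z_thresh: float = Z_THRESH_DEFAULT,
    n_perm: int = 1000,
    seed: int = 0,
) -> list:
    """Group apple-minus-cup mean-activation clusters (two-sided).

    ``subject_results`` are :class:`FirstLevelFit` objects from condition
    designs.  On synthetic data whose prime effect is a mean-free spatial
    pattern this whole-brain test should return no clusters, while the
    searchlight decoder still finds the pattern.
    """
    maps = []
    for fl in subject_results:
        m = fl.contrast_map({"apple": 1.0, "cup": -1.0})
        maps.append(smooth_map(m, fwhm_mm, voxel_size_mm))
    return group_cluster_fwe(
        maps,
        mask,
        z_thresh=z_thresh,
        n_perm=n_perm,
        seed=seed,
        two_sided=True,
    )
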