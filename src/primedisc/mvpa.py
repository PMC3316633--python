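"""FIR deconvolution and searchlight decoding with leave-one-run-out CV.

For a two-class trial dichotomy (apple/cup prime, now/later outcome,
easy/hard difficulty) a finite-impulse-response model estimates, per run
and class, one response parameter for each of six 2000 ms time bins after
the visual onset (12 condition regressors per run for prime decoding),
after 128 s high-pass filtering.  Decoding then moves a sphere (radius 3
voxels) across the grid: at every centre the per-run, per-class FIR
patterns at the analysed bins (the last two) form one pattern vector per
class per run, a linear support-vector classifier (C = 1) is trained on
all runs but one and tested on the held-out run, and accuracy is averaged
over folds and bins.  Chance is 50% by construction (one vector per class
per run).  Group inference smooths accuracy-minus-chance maps and reuses
the sign-flip cluster-FWE machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import sklearn
from scipy import ndimage
from sklearn.svm import SVC

from .bold import VolumeSeries, cosine_drift_basis, smooth_map
from .discounting import PRIME_APPLE, PRIME_CONTROL, PRIME_CUP
from .glm import group_cluster_fwe

__all__ = [
    "FirEstimates",
    "AccuracyMap",
    "SubjectExcluded",
    "prime_labels",
    "outcome_labels",
    "difficulty_labels",
    "fit_fir",
    "sphere_offsets",
    "searchlight_decode",
    "group_accuracy_inference",
    "within_condition_difficulty_decode",
]

N_BINS_DEFAULT = 6
BIN_WIDTH_MS_DEFAULT = 2000.0
ANALYSED_BINS_DEFAULT = (5, 6)  # 1-based: the last two bins
MIN_TRIALS_PER_CLASS = 4
MIN_USABLE_RUNS = 3


class SubjectExcluded(RuntimeError):
    """Too few balanced runs to decode this subject."""


@dataclass
class FirEstimates:
    """Per run x class x time-bin parameter estimates over mask voxels."""

    betas: np.ndarray  # n_runs x 2 x n_bins x n_voxels
    classes: tuple
    runs: list  # run numbers retained
    n_bins: int
    bin_width_ms: float
    mask: np.ndarray
    grid: tuple
    voxel_size_mm: float


@dataclass
class AccuracyMap:
    """Cross-validated decoding accuracy per centre voxel (NaN off-mask)."""

    accuracy: np.ndarray
    chance: float
    radius: int
    label_pair: tuple
    n_folds: int

    def mean_accuracy(self, region_mask=None) -> float:
        acc = self.accuracy if region_mask is None else self.accuracy[region_mask]
        return float(np.nanmean(acc))


def prime_labels(events: pd.DataFrame) -> pd.Series:
    """apple/cup labels on TD trials, NA elsewhere."""
    lab = pd.Series(pd.NA, index=events.index, dtype="object")
    lab[events["prime"] == PRIME_APPLE] = "apple"
    lab[events["prime"] == PRIME_CUP] = "cup"
    return lab


def outcome_labels(events: pd.DataFrame) -> pd.Series:
    """now/later labels on answered TD trials, NA elsewhere."""
    lab = pd.Series(pd.NA, index=events.index, dtype="object")
    td = events["prime"] != PRIME_CONTROL
    for c in ("now", "later"):
        lab[td & (events["choice"] == c)] = c
    return lab


def difficulty_labels(events: pd.DataFrame, hard: pd.Series) -> pd.Series:
    """easy/hard labels from a median-split boolean series."""
    lab = pd.Series(pd.NA, index=events.index, dtype="object")
    lab[hard == True] = "hard"  # noqa: E712  (nullable boolean)
    lab[hard == False] = "easy"  # noqa: E712
    return lab


def fit_fir(
    volumes: VolumeSeries,
    events: pd.DataFrame,
    labels: pd.Series,
    n_bins: int = N_BINS_DEFAULT,
    bin_width_ms: float = BIN_WIDTH_MS_DEFAULT,
    highpass_s: float = 128.0,
    min_trials_per_class: int = MIN_TRIALS_PER_CLASS,
    min_usable_runs: int = MIN_USABLE_RUNS,
) -> FirEstimates:
    """Least-squares FIR estimates per run and class.

    Bin 1 starts at the volume containing the trial's visual onset; the
    six bins cover 12 s.  A run with fewer than ``min_trials_per_class``
    labelled trials of either class is excluded; a subject with fewer than
    ``min_usable_runs`` usable runs raises :class:`SubjectExcluded`.
    """
    classes = tuple(sorted(pd.unique(labels.dropna())))
    if len(classes) != 2:
        raise ValueError(f"labels must form a dichotomy, got {classes}")
    tr_s = volumes.tr_s
    if abs(bin_width_ms / 1000.0 - tr_s) > 1e-9:
        raise ValueError("bin width must equal one TR")
    T = volumes.volumes_per_run
    drift = cosine_drift_basis(T, tr_s, highpass_s)
    usable_runs, betas_list = [], []
    run_numbers = sorted(events["run"].unique())
    if len(run_numbers) != volumes.n_runs:
        raise ValueError("events runs do not match the volumes")
    for ri, run in enumerate(run_numbers):
        ev = events.loc[events["run"] == run]
        lab = labels.loc[ev.index]
        counts = lab.value_counts()
        if any(counts.get(c, 0) < min_trials_per_class for c in classes):
            continue
        def bin_sticks(onsets_s):
            onset_vol = np.floor(np.asarray(onsets_s, dtype=float) / tr_s).astype(int)
            out = []
            for b in range(n_bins):
                reg = np.zeros(T)
                idx = onset_vol + b
                idx = idx[idx < T]
                np.add.at(reg, idx, 1.0)
                out.append(reg)
            return out

        cols = []
        for c in classes:
            cols.extend(bin_sticks(ev.loc[lab == c, "stim_onset_s"]))
        # trials outside the decoded dichotomy (perceptual control, missed,
        # other prime condition) are modelled as one nuisance FIR set so
        # their evoked signal cannot alias into the condition estimates
        other = ev.loc[lab.isna()]
        nuisance = bin_sticks(other["stim_onset_s"]) if len(other) else []
        nuisance = [r for r in nuisance if r.any()]
        X = np.column_stack(cols + nuisance + [drift, np.ones(T)])
        Y = volumes.run_data(ri).T  # time x voxels
        b, *_ = np.linalg.lstsq(X, Y, rcond=None)
        betas_list.append(
            b[: 2 * n_bins].reshape(2, n_bins, -1)
        )
        usable_runs.append(run)
    if len(usable_runs) < min_usable_runs:
        raise SubjectExcluded(
            f"only {len(usable_runs)} balanced runs "
            f"(need {min_usable_runs}) for classes {classes}"
        )
    return FirEstimates(
        betas=np.stack(betas_list),
        classes=classes,
        runs=usable_runs,
        n_bins=n_bins,
        bin_width_ms=bin_width_ms,
        mask=volumes.mask,
        grid=volumes.grid,
        voxel_size_mm=volumes.voxel_size_mm,
    )


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer lattice offsets with Euclidean norm <= radius (centre included)."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    r = int(np.floor(radius))
    g = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(g, g, g, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def _neighbor_table(mask: np.ndarray, radius: int, centers: np.ndarray):
    """For each centre voxel, the flat-mask indices of its in-mask sphere.

    Returns (neighbors, counts): an int array (n_centers x n_offsets) with
    -1 padding, and per-centre voxel counts.  Spheres truncated at the grid
    edge or mask boundary simply use the voxels available.
    """
    offs = sphere_offsets(radius)
    flat_index = np.full(mask.shape, -1, dtype=int)
    flat_index[mask] = np.arange(int(mask.sum()))
    coords = centers  # n_centers x 3
    n_c = coords.shape[0]
    neighbors = np.full((n_c, len(offs)), -1, dtype=int)
    shape = np.array(mask.shape)
    for j, off in enumerate(offs):
        p = coords + off
        ok = np.all((p >= 0) & (p < shape), axis=1)
        idx = np.full(n_c, -1, dtype=int)
        idx[ok] = flat_index[p[ok, 0], p[ok, 1], p[ok, 2]]
        neighbors[:, j] = idx
    counts = (neighbors >= 0).sum(axis=1)
    return neighbors, counts


def _sphere_gram_stack(fir: FirEstimates, bins, radius: int) -> np.ndarray:
    """Linear-kernel Gram matrices of every searchlight sphere at once.

    For samples i, j the sphere Gram entry at centre c is
    ``sum_{v in sphere(c)} d_i(v) d_j(v)`` — a spherical box-sum of the
    voxelwise product map, computed for all centres with one spatial
    correlation per sample pair.  Out-of-mask voxels contribute zero,
    which reproduces sphere truncation at the mask edge exactly.
    Returns an array (n_bins, n_samples, n_samples) + grid.
    """
    n_runs = fir.betas.shape[0]
    n_samples = n_runs * 2
    offs = sphere_offsets(radius)
    r = int(np.max(np.abs(offs)))
    side = 2 * r + 1
    footprint = np.zeros((side, side, side))
    footprint[offs[:, 0] + r, offs[:, 1] + r, offs[:, 2] + r] = 1.0
    grams = np.zeros((len(bins), n_samples, n_samples) + fir.grid)
    vols = np.zeros((len(bins), n_samples) + fir.grid)
    for bi, b in enumerate(bins):
        flat = fir.betas[:, :, b, :].reshape(n_samples, -1)
        for i in range(n_samples):
            vols[bi, i][fir.mask] = flat[i]
    for bi in range(len(bins)):
        for i in range(n_samples):
            for j in range(i, n_samples):
                s = ndimage.correlate(
                    vols[bi, i] * vols[bi, j], footprint, mode="constant"
                )
                grams[bi, i, j] = s
                grams[bi, j, i] = s
    return grams


def _batched_svm_solve(K, y, C=1.0, max_sweeps=300, tol=1e-9):
    """Dual SMO for many small soft-margin SVMs with shared labels.

    ``K``: (P, n, n) precomputed kernels; ``y``: (n,) in {-1, +1}.  Pair
    updates sweep deterministically over all index pairs, vectorised over
    the P problems.  Returns (alpha, f, b) with ``f_i = sum_k a_k y_k K_ik``
    and the bias from the Keerthi KKT interval.  Solves the same QP as a
    C-SVM with precomputed kernel; an equivalence test pins it against the
    reference implementation.
    """
    P, n, _ = K.shape
    alpha = np.zeros((P, n))
    f = np.zeros((P, n))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for _ in range(max_sweeps):
        max_change = 0.0
        for i, j in pairs:
            s = y[i] * y[j]
            e_diff = (f[:, i] - y[i]) - (f[:, j] - y[j])
            eta = K[:, i, i] + K[:, j, j] - 2.0 * K[:, i, j]
            ok = eta > 1e-12
            aj_new = alpha[:, j] + y[j] * e_diff / np.where(ok, eta, 1.0)
            if s == 1:
                lo = np.maximum(0.0, alpha[:, i] + alpha[:, j] - C)
                hi = np.minimum(C, alpha[:, i] + alpha[:, j])
            else:
                lo = np.maximum(0.0, alpha[:, j] - alpha[:, i])
                hi = np.minimum(C, C + alpha[:, j] - alpha[:, i])
            aj_new = np.clip(aj_new, lo, hi)
            d_j = np.where(ok, aj_new - alpha[:, j], 0.0)
            d_i = -s * d_j
            alpha[:, j] += d_j
            alpha[:, i] += d_i
            f += (d_i * y[i])[:, None] * K[:, :, i] + (d_j * y[j])[:, None] * K[
                :, :, j
            ]
            change = np.abs(d_j).max() if len(d_j) else 0.0
            max_change = max(max_change, change)
        if max_change < tol:
            break
    # bias from the KKT interval (midpoint; collapses for free SVs)
    g = y[None, :] - f
    up = ((y > 0) & (alpha < C - 1e-12)) | ((y < 0) & (alpha > 1e-12))
    dn = ((y > 0) & (alpha > 1e-12)) | ((y < 0) & (alpha < C - 1e-12))
    b_lo = np.where(up, g, -np.inf).max(axis=1)
    b_hi = np.where(dn, g, np.inf).min(axis=1)
    b_lo = np.where(np.isfinite(b_lo), b_lo, b_hi)
    b_hi = np.where(np.isfinite(b_hi), b_hi, b_lo)
    b = 0.5 * (b_lo + b_hi)
    return alpha, f, b


def _batched_svm_cv(G_all, y01, run_of_sample, C=1.0):
    """Leave-one-run-out CV correct-counts for all centres at once.

    ``G_all``: (n_samples, n_samples, P) sphere Gram matrices; ``y01``
    labels in {0, 1}.  Kernels are double-centred on the training fold
    (a feature translation, absorbed by the bias) for conditioning.
    Returns (correct, total) arrays of length P.
    """
    n = len(y01)
    y = np.where(np.asarray(y01) > 0, 1.0, -1.0)
    P = G_all.shape[2]
    correct = np.zeros(P)
    total = np.zeros(P)
    runs = np.unique(run_of_sample)
    M = np.moveaxis(G_all, 2, 0)  # P x n x n
    for held in runs:
        tr = run_of_sample != held
        te = ~tr
        idx_tr = np.flatnonzero(tr)
        idx_te = np.flatnonzero(te)
        r = M[:, :, idx_tr].mean(axis=2)  # P x n: row means over train cols
        m = r[:, idx_tr].mean(axis=1)  # P: grand mean over train block
        K = (
            M[np.ix_(np.arange(P), idx_tr, idx_tr)]
            - r[:, idx_tr, None]
            - r[:, None, idx_tr]
            + m[:, None, None]
        )
        alpha, _, b = _batched_svm_solve(K, y[idx_tr], C=C)
        k_te = (
            M[np.ix_(np.arange(P), idx_te, idx_tr)]
            - r[:, idx_te, None]
            - r[:, None, idx_tr]
            + m[:, None, None]
        )
        dec = np.einsum("pti,pi->pt", k_te, alpha * y[idx_tr]) + b[:, None]
        pred = np.where(dec > 0, 1.0, -1.0)
        correct += (pred == y[idx_te][None, :]).sum(axis=1)
        total += len(idx_te)
    return correct, total


def searchlight_decode(
    fir: FirEstimates,
    radius: int = 3,
    analysed_bins: tuple = ANALYSED_BINS_DEFAULT,
    C: float = 1.0,
    centers_mask: np.ndarray | None = None,
    concat_bins: bool = False,
    method: str = "gram",
) -> AccuracyMap:
    """Leave-one-run-out searchlight accuracy map.

    At each centre, the per-run per-class pattern vectors over the sphere's
    in-mask voxels are classified with a linear support-vector machine
    (fixed C).  ``analysed_bins`` are 1-based; by default the accuracies of
    the last two bins are averaged (set ``concat_bins`` to concatenate the
    bins into one pattern vector instead).  ``centers_mask`` restricts the
    centre voxels (the full analysis mask by default).

    ``method='gram'`` precomputes every sphere's linear-kernel Gram matrix
    with spatial correlations and trains on the precomputed kernel;
    ``method='direct'`` extracts explicit feature vectors per sphere.  The
    two are algebraically identical (the SVM decision function depends on
    the training data only through inner products, and a common feature
    translation is absorbed by the bias term).
    """
    n_runs = fir.betas.shape[0]
    if n_runs < 3:
        raise SubjectExcluded("need at least 3 usable runs for cross-validation")
    bins = [b - 1 for b in analysed_bins]
    if any(b < 0 or b >= fir.n_bins for b in bins):
        raise ValueError(f"analysed bins {analysed_bins} outside 1..{fir.n_bins}")
    mask = fir.mask
    if centers_mask is None:
        centers_mask = mask
    centers = np.argwhere(centers_mask & mask)
    n_centers = centers.shape[0]
    y = np.tile(np.array([0, 1]), n_runs)
    run_of_sample = np.repeat(np.arange(n_runs), 2)

    acc = np.full(mask.shape, np.nan)
    correct = np.zeros(n_centers)
    total = np.zeros(n_centers)

    if method == "gram":
        grams = _sphere_gram_stack(fir, bins, radius)
        if concat_bins:
            grams = grams.sum(axis=0, keepdims=True)
        cx, cy, cz = centers[:, 0], centers[:, 1], centers[:, 2]
        for bi in range(grams.shape[0]):
            G_all = grams[bi][:, :, cx, cy, cz]  # n_samp x n_samp x n_centers
            c_b, t_b = _batched_svm_cv(G_all, y, run_of_sample, C=C)
            correct += c_b
            total += t_b
    elif method == "direct":
        neighbors, counts = _neighbor_table(mask, radius, centers)
        per_bin = [fir.betas[:, :, b, :].reshape(n_runs * 2, -1) for b in bins]
        clf = SVC(kernel="linear", C=C)
        with sklearn.config_context(assume_finite=True):
            for ci in range(n_centers):
                if counts[ci] == 0:
                    continue
                vox = neighbors[ci][neighbors[ci] >= 0]
                if concat_bins:
                    data_sets = [
                        np.concatenate([d[:, vox] for d in per_bin], axis=1)
                    ]
                else:
                    data_sets = [d[:, vox] for d in per_bin]
                for X in data_sets:
                    for held in range(n_runs):
                        train = run_of_sample != held
                        mu = X[train].mean(axis=0)
                        clf.fit(X[train] - mu, y[train])
                        pred = clf.predict(X[~train] - mu)
                        correct[ci] += (pred == y[~train]).sum()
                        total[ci] += 2
    else:
        raise ValueError(f"unknown method {method!r}")

    ok = total > 0
    acc[centers[ok, 0], centers[ok, 1], centers[ok, 2]] = correct[ok] / total[ok]
    return AccuracyMap(
        accuracy=acc,
        chance=0.5,
        radius=radius,
        label_pair=fir.classes,
        n_folds=n_runs,
    )


def group_accuracy_inference(
    maps: list,
    mask: np.ndarray,
    fwhm_mm: float = 8.0,
    voxel_size_mm: float = 4.0,
    z_thresh: float = 1.96,
    n_perm: int = 1000,
    seed: int = 0,
) -> list:
    """Cluster-FWE one-sample inference on accuracy-minus-chance maps."""
    smoothed = [
        smooth_map(m.accuracy - m.chance, fwhm_mm, voxel_size_mm) for m in maps
    ]
    return group_cluster_fwe(
        smoothed, mask, z_thresh=z_thresh, n_perm=n_perm, seed=seed
    )


def within_condition_difficulty_decode(
    volumes: VolumeSeries,
    events: pd.DataFrame,
    params,
    radius: int = 3,
    **searchlight_kwargs,
) -> dict:
    """Easy/hard decoding run separately within each prime condition.

    The median split on the difficulty index is recomputed within each
    condition (so both classes exist in each analysis); run and subject
    exclusions follow the FIR balance rule.  Returns a dict
    prime -> AccuracyMap.
    """
    from .discounting import difficulty_index

    out = {}
    for prime in (PRIME_APPLE, PRIME_CUP):
        sel = (events["prime"] == prime).to_numpy()
        gamma = difficulty_index(
            events.loc[sel, "prime"].to_numpy(),
            events.loc[sel, "amount"].to_numpy(),
            events.loc[sel, "delay"].to_numpy(),
            params,
        )
        lab = pd.Series(pd.NA, index=events.index, dtype="object")
        lab.loc[sel] = np.where(gamma > np.median(gamma), "hard", "easy")
        fir = fit_fir(volumes, events, lab)
        out[prime] = searchlight_decode(fir, radius=radius, **searchlight_kwargs)
    return out
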