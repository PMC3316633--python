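"""FIR deconvolution and searchlight decoding."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from primedisc import DesignConfig, DiscountParams, build_design
from primedisc.mvpa import (
    SubjectExcluded,
    difficulty_labels,
    fit_fir,
    outcome_labels,
    prime_labels,
    searchlight_decode,
    sphere_offsets,
    within_condition_difficulty_decode,
)
from primedisc.simulate import BoldSpec, PlantedRegion, simulate_bold, simulate_choices

P = DiscountParams(k=0.024, a=0.06, omega=0.3)
SMALL = BoldSpec(grid=(10, 10, 8))


@pytest.fixture(scope="module")
def dataset(schedule):
    return simulate_choices(P, schedule, seed=41)


@pytest.fixture(scope="module")
def pattern_bold(schedule, dataset):
    region = (PlantedRegion((5, 5, 3), (4, 4, 4), "prime_pattern", 3.0),)
    spec = dataclasses.replace(SMALL, grid=(14, 14, 10), regions=region)
    return simulate_bold(schedule, P, dataset, spec, seed=77)


@pytest.mark.parametrize("radius, expected", [(1, 7), (2, 33), (3, 123)])
def test_sphere_offsets_counts(radius, expected):
    offs = sphere_offsets(radius)
    assert len(offs) == expected
    # brute-force lattice enumeration as the oracle
    count = sum(
        1
        for x in range(-radius, radius + 1)
        for y in range(-radius, radius + 1)
        for z in range(-radius, radius + 1)
        if x * x + y * y + z * z <= radius * radius
    )
    assert len(offs) == count
    assert (offs == 0).all(axis=1).any()  # centre included


def test_fir_design_has_twelve_condition_columns(schedule, dataset):
    """Prime decoding: 2 classes x 6 bins = 12 condition regressors/run."""
    spec = dataclasses.replace(SMALL, grid=(6, 6, 4))
    vols, _ = simulate_bold(schedule, P, dataset, spec, seed=5)
    fir = fit_fir(vols, dataset, prime_labels(dataset))
    assert fir.betas.shape[:3] == (6, 2, 6)
    assert fir.classes == ("apple", "cup")


def test_fir_noiseless_recovery(schedule, dataset):
    """With zero noise the planted per-class response is recovered exactly."""
    spec = dataclasses.replace(
        SMALL, noise_sd=0.0, drift_amplitude=0.0,
        regions=(PlantedRegion((2, 2, 2), (3, 3, 3), "prime_pattern", 1.0),),
    )
    vols, truth = simulate_bold(schedule, P, dataset, spec, seed=6)
    fir = fit_fir(vols, dataset, prime_labels(dataset))
    diff = fir.betas[:, 0] - fir.betas[:, 1]  # runs x bins x vox
    flat = np.full(spec.grid, -1, int)
    flat[vols.mask] = np.arange(vols.mask.sum())
    out_vox = flat[vols.mask & ~truth["prime_pattern:0"]]
    assert np.abs(diff[..., out_vox]).max() < 1e-9
    in_vox = flat[truth["prime_pattern:0"] & vols.mask]
    assert np.abs(diff[..., in_vox]).max() > 0.1


def test_unbalanced_runs_excluded():
    sched = build_design(DesignConfig(seed=3), P.k)
    ds = simulate_choices(P, sched, seed=3)
    labels = prime_labels(ds)
    # blank out apple trials in runs 1-4 -> those runs unusable
    labels[(ds["run"] <= 4) & (ds["prime"] == "apple")] = pd.NA
    spec = dataclasses.replace(SMALL, grid=(6, 6, 4))
    vols, _ = simulate_bold(sched, P, ds, spec, seed=8)
    with pytest.raises(SubjectExcluded):
        fit_fir(vols, ds, labels)
    fir = fit_fir(vols, ds, labels, min_usable_runs=2)
    assert fir.runs == [5, 6]


def test_searchlight_recovers_planted_prime_pattern(pattern_bold, dataset):
    vols, truth = pattern_bold
    fir = fit_fir(vols, dataset, prime_labels(dataset))
    amap = searchlight_decode(fir, radius=2)
    in_region = amap.mean_accuracy(truth["prime_pattern:0"])
    # "far" voxels: centres whose radius-2 sphere cannot touch the region
    from scipy.ndimage import binary_dilation

    dilated = binary_dilation(truth["prime_pattern:0"], iterations=3)
    far = vols.mask & ~dilated
    out_region = amap.mean_accuracy(far)
    assert in_region > 0.8
    assert abs(out_region - 0.5) < 0.1
    assert np.nanmax(amap.accuracy) <= 1.0 and np.nanmin(amap.accuracy) >= 0.0
    assert amap.n_folds == 6
    # radius-3 replication finds the same region
    amap3 = searchlight_decode(fir, radius=3, centers_mask=truth["prime_pattern:0"])
    assert amap3.mean_accuracy(truth["prime_pattern:0"]) > 0.8


def test_searchlight_invariant_to_label_swap(pattern_bold, dataset):
    vols, truth = pattern_bold
    fir = fit_fir(vols, dataset, prime_labels(dataset))
    swapped = dataclasses.replace(
        fir, betas=fir.betas[:, ::-1].copy(), classes=("cup", "apple")
    )
    center = truth["prime_pattern:0"]
    a1 = searchlight_decode(fir, radius=2, centers_mask=center)
    a2 = searchlight_decode(swapped, radius=2, centers_mask=center)
    np.testing.assert_allclose(
        a1.accuracy[center], a2.accuracy[center], atol=1e-12
    )


def test_early_bins_carry_no_decision_information(pattern_bold, dataset):
    """The planted stimulus-locked pattern is read out from late bins; the
    response has not built up in bin 1."""
    vols, truth = pattern_bold
    fir = fit_fir(vols, dataset, prime_labels(dataset))
    center = truth["prime_pattern:0"]
    early = searchlight_decode(fir, radius=2, analysed_bins=(1,), centers_mask=center)
    late = searchlight_decode(fir, radius=2, analysed_bins=(5, 6), centers_mask=center)
    assert late.mean_accuracy(center) > 0.8
    assert early.mean_accuracy(center) < 0.65


def test_concat_bins_variant(pattern_bold, dataset):
    vols, truth = pattern_bold
    fir = fit_fir(vols, dataset, prime_labels(dataset))
    center = truth["prime_pattern:0"]
    cat = searchlight_decode(fir, radius=2, centers_mask=center, concat_bins=True)
    assert cat.mean_accuracy(center) > 0.8


def test_outcome_and_difficulty_labels(dataset):
    out = outcome_labels(dataset)
    td = dataset["prime"] != "control"
    assert out[td].isin(["now", "later"]).all()
    assert out[~td].isna().all()
    from primedisc.discounting import label_difficulty

    hard = label_difficulty(dataset, P)
    lab = difficulty_labels(dataset, hard)
    assert set(lab.dropna()) == {"easy", "hard"}


def test_within_condition_difficulty_decoding(schedule):
    ds = simulate_choices(P, schedule, seed=55)
    region = (PlantedRegion((2, 2, 2), (5, 5, 4), "difficulty_pattern", 3.0),)
    spec = dataclasses.replace(SMALL, grid=(8, 8, 6), regions=region)
    vols, truth = simulate_bold(schedule, P, ds, spec, seed=56)
    maps = within_condition_difficulty_decode(vols, ds, P, radius=2)
    for prime in ("apple", "cup"):
        assert maps[prime].mean_accuracy(truth["difficulty_pattern:0"]) > 0.6


def test_group_accuracy_inference(rng):
    """Smoothed accuracy-minus-chance group test finds a planted cluster
    and stays silent on null maps."""
    from primedisc.mvpa import AccuracyMap, group_accuracy_inference

    mask = np.ones((12, 12, 8), bool)
    signal = np.zeros(mask.shape)
    signal[4:8, 4:8, 2:6] = 0.08  # 8 accuracy points above chance

    def make(maps_signal):
        return [
            AccuracyMap(
                accuracy=0.5 + maps_signal + 0.04 * rng.standard_normal(mask.shape),
                chance=0.5,
                radius=3,
                label_pair=("apple", "cup"),
                n_folds=6,
            )
            for _ in range(8)
        ]

    clusters = group_accuracy_inference(make(signal), mask, n_perm=256, seed=2)
    assert clusters
    assert signal[clusters[0].peak_ijk] > 0
    assert group_accuracy_inference(make(0.0), mask, n_perm=256, seed=2) == []


def test_gram_and_direct_searchlight_agree(pattern_bold, dataset):
    """The precomputed-Gram decoding path reproduces the explicit
    feature-extraction path voxel for voxel."""
    vols, _ = pattern_bold
    fir = fit_fir(vols, dataset, prime_labels(dataset))
    g = searchlight_decode(fir, radius=2, method="gram")
    d = searchlight_decode(fir, radius=2, method="direct")
    m = vols.mask
    agree = np.nanmean(g.accuracy[m] == d.accuracy[m])
    assert agree > 0.99  # rare single-classification flips at SMO tolerance
    assert np.nanmean(g.accuracy) == pytest.approx(np.nanmean(d.accuracy), abs=1e-3)


def test_batched_svm_matches_reference_svc(rng):
    """The vectorised dual solver reproduces the reference SVC decisions
    on random leave-one-run-out problems."""
    import sklearn
    from sklearn.svm import SVC

    from primedisc.mvpa import _batched_svm_cv

    y = np.tile([0, 1], 6)
    run = np.repeat(np.arange(6), 2)
    clf = SVC(kernel="linear", C=1)
    mismatches = 0
    total = 0
    for _ in range(100):
        X = rng.standard_normal((12, 40)) + 5.0 * rng.standard_normal(40)
        c_b, t_b = _batched_svm_cv((X @ X.T)[:, :, None], y, run)
        c_ref = 0
        with sklearn.config_context(assume_finite=True):
            for held in range(6):
                tr = run != held
                mu = X[tr].mean(axis=0)
                clf.fit(X[tr] - mu, y[tr])
                c_ref += (clf.predict(X[~tr] - mu) == y[~tr]).sum()
        mismatches += abs(c_b[0] - c_ref)
        total += t_b[0]
    assert mismatches / total < 0.01


def test_searchlight_requires_enough_runs(pattern_bold, dataset):
    vols, _ = pattern_bold
    fir = fit_fir(vols, dataset, prime_labels(dataset))
    crippled = dataclasses.replace(fir, betas=fir.betas[:2])
    with pytest.raises(SubjectExcluded):
        searchlight_decode(crippled)
    with pytest.raises(ValueError):
        searchlight_decode(fir, analysed_bins=(0, 7))
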