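"""Parametric designs, OLS recovery and cluster-level permutation inference."""

import dataclasses

import numpy as np
import pytest

from primedisc import DiscountParams
from primedisc.bold import VolumeSeries, hrf_kernel, smooth_map
from primedisc.glm import (
    build_condition_design,
    build_interaction_design,
    build_premium_design,
    condition_contrast_null,
    fit_glm,
    group_cluster_fwe,
)
from primedisc.simulate import BoldSpec, PlantedRegion, simulate_bold, simulate_choices

P = DiscountParams(k=0.024, a=0.06, omega=0.3)


@pytest.fixture(scope="module")
def dataset(schedule):
    return simulate_choices(P, schedule, seed=41)


def test_hrf_kernel_shape():
    kernel, dt = hrf_kernel(2000.0, oversampling=16)
    assert kernel.max() == pytest.approx(1.0)
    peak_t = np.argmax(kernel) * dt
    assert peak_t == pytest.approx(6.0, abs=2 * dt)
    assert kernel.sum() * dt > 0  # net positive response
    k2, _ = hrf_kernel(2000.0, oversampling=16)
    assert np.array_equal(kernel, k2)


def test_hrf_matches_reference_implementation():
    """Shape agrees with the canonical kernel from an established
    neuroimaging library (up to scaling)."""
    nilearn = pytest.importorskip("nilearn.glm.first_level")
    kernel, dt = hrf_kernel(2000.0, oversampling=16)
    ref = nilearn.spm_hrf(2.0, oversampling=16, time_length=32.0)
    n = min(len(kernel), len(ref))
    r = np.corrcoef(kernel[:n], ref[:n])[0, 1]
    assert r > 0.95


def test_interaction_design_orthogonality(dataset):
    designs = build_interaction_design(dataset, P, n_scans=189, tr_s=2.0)
    assert len(designs) == 6
    for d in designs:
        assert "sv_mod" in d.columns and "sigma_mod" in d.columns
        sv = d.col("sv_mod")
        sigma = d.col("sigma_mod")
        assert abs(sigma @ sv) < 1e-8
        for name in ("apple", "cup", "control"):
            assert abs(sigma @ d.col(name)) < 1e-8
        # no column identically zero
        assert all(np.abs(d.matrix[:, j]).max() > 0 for j in range(d.matrix.shape[1]))


def test_interaction_design_reverse_order(dataset):
    fwd = build_interaction_design(dataset, P, 189, 2.0)[0]
    rev = build_interaction_design(dataset, P, 189, 2.0, reverse_order=True)[0]
    # order swaps which modulator keeps the shared variance
    i_fwd = fwd.columns.index("sv_mod")
    i_rev = rev.columns.index("sigma_mod")
    assert i_fwd < fwd.columns.index("sigma_mod")
    assert i_rev < rev.columns.index("sv_mod")


def test_zero_premium_drops_sigma_column(dataset):
    a0 = DiscountParams(k=0.024, a=0.0, omega=0.3)
    designs = build_interaction_design(dataset, a0, 189, 2.0)
    assert all("sigma_mod" not in d.columns for d in designs)


def test_premium_design_structure(dataset):
    designs = build_premium_design(dataset, P, 189, 2.0)
    for d in designs:
        assert "pi_mod" in d.columns
        assert abs(d.col("pi_mod") @ d.col("sv_mod")) < 1e-8
    # restricting to correctly predicted trials with a perfect predictor
    # changes nothing
    all_correct = np.ones(len(dataset), dtype=bool)
    same = build_premium_design(dataset, P, 189, 2.0, correct_only=all_correct)
    for d1, d2 in zip(designs, same):
        assert np.allclose(d1.matrix, d2.matrix)


def _small_bold(dataset, schedule, regions=(), noise=0.0, seed=5, **kw):
    spec = BoldSpec(
        grid=(10, 10, 8),
        regions=regions,
        noise_sd=noise,
        drift_amplitude=kw.pop("drift", 0.0),
        **kw,
    )
    return simulate_bold(schedule, P, dataset, spec, seed=seed)


def test_noiseless_parametric_recovery(schedule, dataset):
    """Betas on noiseless planted data scale with planted amplitudes."""
    regions = (
        PlantedRegion((1, 1, 1), (3, 3, 3), "sv_parametric", amplitude=1.0),
        PlantedRegion((6, 6, 4), (3, 3, 3), "sv_parametric", amplitude=2.0),
    )
    vols, truth = _small_bold(dataset, schedule, regions)
    designs = build_interaction_design(dataset, P, 189, 2.0)
    fl = fit_glm(vols, designs)
    eff = fl.contrast_map("sv_mod")
    m1 = np.nanmean(eff[truth["sv_parametric:0"]])
    m2 = np.nanmean(eff[truth["sv_parametric:1"]])
    out = ~(truth["sv_parametric:0"] | truth["sv_parametric:1"]) & vols.mask
    assert m1 > 10 * abs(np.nanmean(eff[out]))
    assert m2 == pytest.approx(2 * m1, rel=0.05)


def test_planted_sv_region_recovered_with_noise(schedule, dataset):
    region = (PlantedRegion((2, 2, 2), (4, 4, 3), "sv_parametric", 1.5),)
    vols, truth = _small_bold(dataset, schedule, region, noise=1.0, drift=1.0)
    designs = build_interaction_design(dataset, P, 189, 2.0)
    fl = fit_glm(vols, designs)
    t = fl.t_map("sv_mod")
    in_t = np.nanmean(t[truth["sv_parametric:0"]])
    out_t = np.nanmean(t[~truth["sv_parametric:0"] & vols.mask])
    assert in_t > out_t + 2.0


def test_planted_premium_region_recovered(schedule, dataset):
    region = (PlantedRegion((2, 2, 2), (4, 4, 3), "premium_parametric", 1.5),)
    vols, truth = _small_bold(dataset, schedule, region, noise=0.5)
    designs = build_premium_design(dataset, P, 189, 2.0)
    fl = fit_glm(vols, designs)
    t = fl.t_map("pi_mod")
    in_t = np.nanmean(np.abs(t[truth["premium_parametric:0"]]))
    out_t = np.nanmean(np.abs(t[~truth["premium_parametric:0"] & vols.mask]))
    assert in_t > out_t + 2.0


def test_duplicated_column_raises(schedule, dataset):
    vols, _ = _small_bold(dataset, schedule)
    designs = build_condition_design(dataset, 189, 2.0)
    bad = designs[0]
    bad.matrix = np.column_stack([bad.matrix, bad.matrix[:, 0]])
    bad.columns = bad.columns + ["apple_copy"]
    with pytest.raises(ValueError, match="collinear"):
        fit_glm(vols, [bad] + designs[1:])


def test_cluster_fwe_threshold_above_max_gives_nothing(rng):
    mask = np.ones((8, 8, 6), bool)
    maps = [rng.standard_normal(mask.shape) for _ in range(8)]
    assert group_cluster_fwe(maps, mask, z_thresh=50.0, n_perm=128, seed=0) == []
    with pytest.raises(ValueError):
        group_cluster_fwe(maps, mask, n_perm=50)
    with pytest.raises(ValueError):
        group_cluster_fwe(maps[:3], mask, n_perm=128)


def test_cluster_fwe_detects_strong_planted_cluster(rng):
    mask = np.ones((10, 10, 8), bool)
    signal = np.zeros(mask.shape)
    signal[3:6, 3:6, 3:5] = 1.5
    maps = [
        smooth_map(signal + 0.8 * rng.standard_normal(mask.shape), 8.0, 4.0)
        for _ in range(10)
    ]
    clusters = group_cluster_fwe(maps, mask, n_perm=500, seed=1)
    assert clusters
    peak = clusters[0].peak_ijk
    assert signal[peak] > 0


def test_cluster_fwe_false_positive_rate(rng):
    """Family-wise error of the sign-flip cluster test stays near the
    nominal 5% over repeated null experiments (exact enumeration of the
    2^8 flips)."""
    mask = np.ones((8, 8, 6), bool)
    hits = 0
    n_exp = 100
    for e in range(n_exp):
        maps = [
            smooth_map(rng.standard_normal(mask.shape), 8.0, 4.0)
            for _ in range(8)
        ]
        if group_cluster_fwe(maps, mask, n_perm=256, seed=e):
            hits += 1
    assert hits / n_exp <= 0.12
    assert hits / n_exp >= 0.0


def test_condition_contrast_null_on_pattern_only_data(schedule, dataset):
    """Mean-free planted patterns yield no univariate apple-vs-cup
    clusters, while a genuine mean difference is detected."""
    from primedisc import DesignConfig, build_design

    pattern = (PlantedRegion((2, 2, 2), (4, 4, 4), "prime_pattern", 3.0),)
    fits = []
    for s in range(8):
        # each synthetic subject gets their own pseudo-randomised schedule,
        # as in a real session
        sub_sched = build_design(DesignConfig(seed=600 + s), P.k)
        ds = simulate_choices(P, sub_sched, seed=600 + s)
        vols, _ = _small_bold(ds, sub_sched, pattern, noise=1.0, seed=700 + s)
        fits.append(fit_glm(vols, build_condition_design(ds, 189, 2.0)))
        mask = vols.mask
    assert condition_contrast_null(fits, mask, n_perm=256, seed=3) == []

    # sanity inversion: an actual mean difference is found
    def mean_diff_bold(ds, seed):
        spec = BoldSpec(grid=(10, 10, 8), noise_sd=1.0, drift_amplitude=0.0)
        vols, _ = simulate_bold(schedule, P, ds, spec, seed=seed)
        bump = np.zeros(spec.grid)
        bump[3:7, 3:7, 2:6] = 1.0
        # add a genuine apple-minus-cup mean activation by hand
        from primedisc.bold import event_regressor, hrf_kernel as hk

        kernel = hk(2000.0)
        for r in range(6):
            ev = ds[ds["run"] == r + 1]
            apple = ev[ev["prime"] == "apple"]
            reg = event_regressor(
                apple["stim_onset_s"], apple["duration_s"], 1.0, 189, 2.0,
                kernel=kernel,
            )
            sl = vols.run_slice(r)
            vols.data[..., sl] += bump[..., None] * reg
        return vols

    fits2 = []
    for s in range(8):
        ds = simulate_choices(P, schedule, seed=600 + s)
        fits2.append(
            fit_glm(mean_diff_bold(ds, 800 + s), build_condition_design(ds, 189, 2.0))
        )
    clusters = condition_contrast_null(fits2, mask, n_perm=256, seed=3)
    assert clusters
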