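"""Synthetic movie generator: determinism, truth fidelity, exact amplitudes."""

import numpy as np
import pytest
from scipy import stats as sps

from sparklet import (
    AcquisitionParams,
    GroundTruthEvent,
    PairedRateScenario,
    SynthConfig,
    generate_movie,
    generate_paired_rates,
)
from sparklet.simulate import SizingError, site_table, truth_to_frame


def test_rate_zero_movie_is_baseline_plus_noise_only():
    cfg = SynthConfig(n_cells=1, sites_per_cell=2, site_rate=0.0,
                      global_event_rate=0.0, noise_sd=0.0, bleach_rate=0.0,
                      rng_seed=1)
    acq = AcquisitionParams(n_frames=100, frame_shape=(64, 64))
    movie, mask, truth = generate_movie(cfg, acq)
    assert truth == []
    inside = mask.labels > 0
    assert np.all(movie.data[:, inside] == cfg.baseline_cell)
    assert np.all(movie.data[:, ~inside] == cfg.baseline_background)


def test_nonglobal_amplitudes_stay_inside_configured_band():
    # detection floor 0.05 and ceiling 0.27 dF/F0 of the observed events
    cfg = SynthConfig(n_cells=2, sites_per_cell=3, site_rate=2.0,
                      amplitude_band=(0.05, 0.27), global_event_rate=0.0,
                      rng_seed=3)
    acq = AcquisitionParams(n_frames=200, frame_shape=(128, 64))
    _, _, truth = generate_movie(cfg, acq)
    amps = [t.amplitude_ff0 for t in truth if not t.is_global]
    assert len(amps) > 10
    assert all(0.05 <= a <= 0.27 for a in amps)


def test_truth_count_within_poisson_99_interval():
    # 20 sites at 1.0 events/s over 13.33 s: expect ~267 events
    cfg = SynthConfig(n_cells=4, sites_per_cell=5, site_rate=1.0,
                      global_event_rate=0.0, noise_sd=0.0, rng_seed=11)
    acq = AcquisitionParams(n_frames=2000, frame_rate=150.0,
                            frame_shape=(192, 192))
    _, _, truth = generate_movie(cfg, acq)
    lam = 20 * 1.0 * acq.duration_s
    lo, hi = sps.poisson.ppf([0.005, 0.995], lam)
    assert lo <= len(truth) <= hi


def test_seed_determinism_bit_identical():
    cfg = SynthConfig(n_cells=1, sites_per_cell=2, site_rate=1.0, rng_seed=5)
    acq = AcquisitionParams(n_frames=150, frame_shape=(64, 64))
    m1, k1, t1 = generate_movie(cfg, acq)
    m2, k2, t2 = generate_movie(cfg, acq)
    assert np.array_equal(m1.data, m2.data)
    assert np.array_equal(k1.labels, k2.labels)
    assert t1 == t2


def test_noise_free_center_pixel_hits_exact_peak():
    # with no noise/bleach the site-centre pixel reaches baseline*(1+amp)
    cfg = SynthConfig(n_cells=1, sites_per_cell=1, site_rate=0.0,
                      global_event_rate=0.0, noise_sd=0.0, bleach_rate=0.0,
                      rng_seed=2)
    acq = AcquisitionParams(n_frames=200, frame_shape=(96, 96))
    site = site_table(cfg, acq).iloc[0]
    ev = GroundTruthEvent(1, int(site.site_row), int(site.site_col),
                          onset_frame=50, duration_s=0.05, amplitude_ff0=0.15)
    movie, _, truth = generate_movie(cfg, acq, events=[ev])
    assert truth == [ev]
    px = movie.data[:, ev.site_row, ev.site_col]
    peak = px.max()
    assert px.argmax() == 50
    assert peak == pytest.approx(cfg.baseline_cell * 1.15, rel=1e-6)


def test_footprint_contained_within_owning_cell():
    # a sparklet near a cell edge must not touch any other cell's pixels
    cfg = SynthConfig(n_cells=4, sites_per_cell=1, site_rate=0.0,
                      global_event_rate=0.0, noise_sd=0.0, rng_seed=4)
    acq = AcquisitionParams(n_frames=80, frame_shape=(96, 96))
    sites = site_table(cfg, acq)
    evs = [
        GroundTruthEvent(int(r.cell_id), int(r.site_row), int(r.site_col),
                         onset_frame=10, duration_s=0.1, amplitude_ff0=0.27)
        for r in sites.itertuples()
        if r.cell_id == 1
    ]
    movie, mask, _ = generate_movie(cfg, acq, events=evs)
    other = (mask.labels > 0) & (mask.labels != 1)
    rel = movie.data[:, other] / cfg.baseline_cell - 1.0
    assert np.abs(rel).max() < 1e-3


def test_explicit_truth_table_is_returned_unmodified():
    cfg = SynthConfig(n_cells=1, sites_per_cell=1, noise_sd=0.0, rng_seed=9)
    acq = AcquisitionParams(n_frames=60, frame_shape=(64, 64))
    site = site_table(cfg, acq).iloc[0]
    evs = [
        GroundTruthEvent(1, int(site.site_row), int(site.site_col), t0, 0.05, 0.1)
        for t0 in (5, 20, 40)
    ]
    _, _, truth = generate_movie(cfg, acq, events=evs)
    assert truth == evs
    assert len(truth_to_frame(truth)) == 3


def test_frame_too_small_raises_sizing_error():
    cfg = SynthConfig(n_cells=9, sites_per_cell=5)
    acq = AcquisitionParams(n_frames=10, frame_shape=(32, 32))
    with pytest.raises(SizingError):
        generate_movie(cfg, acq)


def test_config_validation():
    with pytest.raises(ValueError):
        SynthConfig(amplitude_band=(0.3, 0.1))
    with pytest.raises(ValueError):
        SynthConfig(site_rate=-1.0)


# ---------------------------------------------------------------------------
# paired-rate scenarios


def test_independent_scenario_rank_correlation_near_zero():
    sc = PairedRateScenario(n_cells=10_000, dependence_model="independent",
                            rng_seed=0)
    tab = generate_paired_rates(sc)
    rs = sps.spearmanr(tab.freq_control, tab.freq_treatment).statistic
    assert abs(rs) < 0.03


def test_proportional_zero_noise_gives_perfect_rank_correlation():
    sc = PairedRateScenario(n_cells=50, dependence_model="proportional-with-noise",
                            generative_rank_correlation=1.0, rng_seed=1)
    tab = generate_paired_rates(sc)
    rs = sps.spearmanr(tab.freq_control, tab.freq_treatment).statistic
    assert rs == pytest.approx(1.0)


def test_independent_identical_marginals_match_in_mean():
    sc = PairedRateScenario(n_cells=10_000, rate_control=0.23,
                            rate_treatment=0.23, rng_seed=2)
    tab = generate_paired_rates(sc)
    pooled_se = np.sqrt(tab.freq_control.var(ddof=1) / len(tab)
                        + tab.freq_treatment.var(ddof=1) / len(tab))
    assert abs(tab.freq_control.mean() - tab.freq_treatment.mean()) < 2 * pooled_se


def test_scenario_validation():
    with pytest.raises(ValueError):
        PairedRateScenario(n_cells=3)
    with pytest.raises(ValueError):
        PairedRateScenario(dependence_model="independent",
                           generative_rank_correlation=0.5)
    with pytest.raises(ValueError):
        PairedRateScenario(rate_control=-0.1)
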