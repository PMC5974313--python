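"""Hopkins statistic: oracle equivalence, calibration, invariances."""

import logging

import numpy as np
import pytest

from nichestat import (
    HopkinsConfig,
    PointPattern,
    SpatialWindow,
    csr_envelope,
    hopkins_group_summary,
    hopkins_resampled,
    hopkins_statistic,
    make_window,
    simulate_csr,
    simulate_perifollicular,
)
from tests.conftest import brute_force_hopkins


def test_hand_computed_corner_square_example():
    """Four corner points of a 10×10 window, fixed origins (5,5),(1,1)
    and data subsample {(0,0),(10,10)}: u = (√50, √2), w = (10, 10),
    so plain h = (√50+√2)/(√50+√2+20)."""
    win = SpatialWindow(width=10, height=10)
    pat = PointPattern(np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float))
    h = hopkins_statistic(
        pat, win, m=2,
        origins=np.array([[5.0, 5.0], [1.0, 1.0]]),
        data_indices=np.array([0, 3]),
    )
    expect = (np.sqrt(50) + np.sqrt(2)) / (np.sqrt(50) + np.sqrt(2) + 20)
    assert h == pytest.approx(expect, abs=1e-15)
    h2 = hopkins_statistic(
        pat, win, m=2, variant="powered",
        origins=np.array([[5.0, 5.0], [1.0, 1.0]]),
        data_indices=np.array([0, 3]),
    )
    assert h2 == pytest.approx(52 / (52 + 200), abs=1e-15)


def test_coincident_points_give_exactly_one(plain_window):
    pat = PointPattern(np.tile([[30.0, 40.0]], (10, 1)))
    assert hopkins_statistic(pat, plain_window, m=5, rng=0) == 1.0
    res = hopkins_resampled(pat, plain_window, HopkinsConfig(m=5, reps=50, seed=1))
    assert res.mean == 1.0 and res.sd == 0.0


def test_range_and_argument_validation(plain_window):
    pat = simulate_csr(30, plain_window, 0)
    for seed in range(20):
        h = hopkins_statistic(pat, plain_window, m=10, rng=seed)
        assert 0.0 <= h <= 1.0
    with pytest.raises(ValueError):
        hopkins_statistic(pat, plain_window, m=31, rng=0)
    single = PointPattern(np.array([[1.0, 1.0]]))
    with pytest.raises(ValueError):
        hopkins_statistic(single, plain_window, m=1, rng=0)


def test_oracle_equivalence_brute_force(plain_window, rng):
    """Fast KD-tree path equals the all-pairs oracle exactly on 100
    random small instances with injected origins and subsamples."""
    for _ in range(100):
        n = int(rng.integers(5, 31))
        m = int(rng.integers(1, min(n, 10) + 1))
        pts = rng.uniform(0, 150, (n, 2))
        origins = rng.uniform(0, 150, (m, 2))
        idx = rng.choice(n, m, replace=False)
        pat = PointPattern(pts)
        for variant, k in [("plain", 1), ("powered", 2)]:
            fast = hopkins_statistic(pat, plain_window, m, variant,
                                     origins=origins, data_indices=idx)
            assert fast == brute_force_hopkins(pts, origins, idx, k)


def test_scale_invariance():
    rng = np.random.default_rng(8)
    pts = rng.uniform(0, 150, (25, 2))
    origins = rng.uniform(0, 150, (6, 2))
    idx = rng.choice(25, 6, replace=False)
    for variant in ("plain", "powered"):
        h1 = hopkins_statistic(PointPattern(pts), SpatialWindow(150, 150), 6,
                               variant, origins=origins, data_indices=idx)
        h2 = hopkins_statistic(PointPattern(pts * 7.5), SpatialWindow(1125, 1125),
                               6, variant, origins=origins * 7.5, data_indices=idx)
        assert h1 == pytest.approx(h2, rel=1e-12)


def test_resampled_reproducible_and_summary(plain_window):
    pat = simulate_csr(120, plain_window, 3)
    cfg = HopkinsConfig(m=40, reps=200, seed=9)
    a = hopkins_resampled(pat, plain_window, cfg)
    b = hopkins_resampled(pat, plain_window, cfg)
    np.testing.assert_array_equal(a.per_rep, b.per_rep)
    assert a.mean == pytest.approx(a.per_rep.mean())
    assert len(a.per_rep) == 200
    assert ((a.per_rep >= 0) & (a.per_rep <= 1)).all()


def test_resampled_reduces_m_with_warning(plain_window, caplog):
    pat = simulate_csr(20, plain_window, 4)
    with caplog.at_level(logging.WARNING, logger="nichestat.hopkins"):
        res = hopkins_resampled(pat, plain_window, HopkinsConfig(m=40, reps=50))
    assert res.config.m == 20
    assert any("reducing m" in r.message for r in caplog.records)


def test_csr_mean_near_half(plain_window):
    """Under CSR the resampled Hopkins mean sits near 0.5."""
    means = []
    for seed in range(5):
        pat = simulate_csr(200, plain_window, seed)
        means.append(hopkins_resampled(
            pat, plain_window, HopkinsConfig(m=40, reps=400, seed=100 + seed)).mean)
    assert 0.47 < np.mean(means) < 0.53


def test_perifollicular_exceeds_matched_csr(follicle_window):
    """Strong perifollicular clustering beats CSR in seed-matched pairs."""
    cfg = lambda s: HopkinsConfig(m=40, reps=300, seed=s)  # noqa: E731
    wins = 0
    for seed in range(20):
        peri = simulate_perifollicular(120, follicle_window, 10, 0.9, seed)
        csr = simulate_csr(120, follicle_window, 5000 + seed)
        h_peri = hopkins_resampled(peri, follicle_window, cfg(seed)).mean
        h_csr = hopkins_resampled(csr, follicle_window, cfg(seed)).mean
        wins += h_peri > h_csr
    assert wins == 20


def test_monotone_in_clustered_fraction(follicle_window):
    """Mean Hopkins rises with the clustered fraction in ≥90% of
    seed-matched (0, 0.4, 0.8) triples."""
    monotone = 0
    n_seeds = 30
    for seed in range(n_seeds):
        means = []
        for j, p in enumerate((0.0, 0.4, 0.8)):
            pat = simulate_perifollicular(120, follicle_window, 10, p,
                                          1000 * j + seed)
            means.append(hopkins_resampled(
                pat, follicle_window,
                HopkinsConfig(m=40, reps=300, seed=seed)).mean)
        monotone += means[0] < means[1] < means[2]
    assert monotone >= 0.9 * n_seeds


def test_envelope_straddles_half_and_validates(plain_window):
    lo, hi, null_means = csr_envelope(
        100, plain_window, HopkinsConfig(m=40, reps=100, seed=5), sims=30)
    assert lo < 0.5 < hi
    assert len(null_means) == 30
    with pytest.raises(ValueError):
        csr_envelope(100, plain_window, HopkinsConfig(), sims=10)


def test_group_summary_hand_example():
    """Textbook pooled two-sample t on the example groups."""
    a = [0.59, 0.62, 0.56]
    b = [0.50, 0.49, 0.51]
    out = hopkins_group_summary({"tg": a, "ctr": b})
    # independent computation of the pooled t statistic
    ma, mb = np.mean(a), np.mean(b)
    sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
    t_hand = (ma - mb) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    assert out["t_statistic"] == pytest.approx(t_hand, rel=1e-12)
    assert out["groups"]["tg"]["mean"] == pytest.approx(ma)
    assert out["groups"]["tg"]["sd"] == pytest.approx(np.std(a, ddof=1))
    assert 0 < out["p_value"] < 0.05


def test_group_summary_identical_groups_t_zero():
    out = hopkins_group_summary({"a": [0.5, 0.6], "b": [0.5, 0.6]})
    assert out["t_statistic"] == pytest.approx(0.0)
    assert out["p_value"] == pytest.approx(1.0)


def test_group_summary_validation():
    with pytest.raises(ValueError):
        hopkins_group_summary({"a": [0.5, 0.6]})
    with pytest.raises(ValueError):
        hopkins_group_summary({"a": [0.5, 0.6], "b": [0.5]})
    with pytest.raises(ValueError):
        hopkins_group_summary({"a": [0.5, 0.6], "b": []})


def test_group_separation_simulated_windows(follicle_window):
    """Six clustered vs six CSR windows separate at α = 0.05."""
    cl, ctr = [], []
    for seed in range(6):
        peri = simulate_perifollicular(120, follicle_window, 10, 0.8, seed)
        csr = simulate_csr(120, follicle_window, 600 + seed)
        cfg = HopkinsConfig(m=40, reps=300, seed=seed)
        cl.append(hopkins_resampled(peri, follicle_window, cfg))
        ctr.append(hopkins_resampled(csr, follicle_window, cfg))
    out = hopkins_group_summary({"clustered": cl, "control": ctr})
    assert out["groups"]["clustered"]["mean"] > out["groups"]["control"]["mean"]
    assert out["p_value"] < 0.05
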