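"""Synthetic EEG generator: planted correlations, determinism, geometry."""

import numpy as np
import pytest

from eegconn.connectivity import build_feature_table
from eegconn.montage import pair_to_index
from eegconn.preprocess import assemble_dataset
from eegconn.simulate import (
    CouplingSpec,
    SimulationConfig,
    make_coupled_pair,
    pink_noise,
    simulate_dataset,
    study_config,
    write_dataset,
)

from conftest import PLANTED_OVERALL


class TestMakeCoupledPair:
    def test_perfect_correlation_is_degenerate(self, rng):
        x, y = make_coupled_pair(4096, 1.0, "overall", 512.0, rng)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(1.0)
        # y is a scalar multiple of x
        assert np.allclose(y, x * (y[0] / x[0]))

    def test_zero_correlation_concentrates_near_zero(self):
        # sampling error of r is ~1/sqrt(n_effective); check the Monte-Carlo
        # mean over many seeds is well inside +/-0.05
        rs = []
        for seed in range(100):
            g = np.random.default_rng(seed)
            x, y = make_coupled_pair(20480, 0.0, "overall", 512.0, g)
            rs.append(np.corrcoef(x, y)[0, 1])
        assert abs(np.mean(rs)) < 0.05
        assert np.percentile(np.abs(rs), 90) < 0.1

    def test_target_correlation_realized(self):
        rs = [
            np.corrcoef(*make_coupled_pair(20480, 0.67, "overall", 512.0,
                                           np.random.default_rng(s)))[0, 1]
            for s in range(30)
        ]
        assert np.mean(rs) == pytest.approx(0.67, abs=0.05)

    def test_unit_variance_and_zero_mean(self, rng):
        x, y = make_coupled_pair(8192, 0.5, "beta", 512.0, rng)
        assert x.mean() == pytest.approx(0.0, abs=1e-10)
        assert x.std() == pytest.approx(1.0, rel=1e-6)
        assert y.std() == pytest.approx(1.0, rel=0.02)

    def test_invalid_r_rejected(self, rng):
        with pytest.raises(ValueError):
            make_coupled_pair(100, 1.5, "overall", 512.0, rng)


class TestConfigValidation:
    def test_duplicate_pair_band_conflict(self):
        c = CouplingSpec(("F7", "T3"), "beta", 0.3, 0.5)
        c2 = CouplingSpec(("T3", "F7"), "beta", 0.1, 0.2)
        with pytest.raises(ValueError, match="conflict"):
            SimulationConfig(couplings=(c, c2))

    def test_same_pair_different_band_allowed(self):
        c = CouplingSpec(("F7", "T3"), "beta", 0.3, 0.5)
        c2 = CouplingSpec(("F7", "T3"), "alpha", 0.1, 0.2)
        SimulationConfig(couplings=(c, c2))

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="not in montage"):
            SimulationConfig(couplings=(CouplingSpec(("F7", "XX"), "beta"),))

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            CouplingSpec(("F7", "F7"), "beta")

    def test_target_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            CouplingSpec(("F7", "T3"), "beta", target_r_group0=1.2)

    def test_noninteger_sample_count_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration_s=1.0001, fs=512.0)


class TestSimulateDataset:
    def test_study_geometry(self, study_recordings):
        """4 subjects/group x 2 groups x 2 tasks -> 16 one-minute recordings."""
        assert len(study_recordings) == 16
        for rec in study_recordings:
            assert rec.data.shape == (19, 30720)
        assert sum(r.group for r in study_recordings) == 8

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_subjects_per_group=1, tasks_per_subject=1,
                               duration_s=2.0, seed=7)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert len(a) == len(b) == 2
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.data, rb.data)

    def test_different_seeds_differ(self):
        base = dict(n_subjects_per_group=1, tasks_per_subject=1, duration_s=2.0)
        a = simulate_dataset(SimulationConfig(seed=1, **base))
        b = simulate_dataset(SimulationConfig(seed=2, **base))
        assert not np.array_equal(a[0].data, b[0].data)

    def test_no_couplings_gives_null_epoch_correlations(self):
        """Independent channels: median per-epoch |r| below 0.1 for all pairs."""
        cfg = SimulationConfig(n_subjects_per_group=1, tasks_per_subject=2, seed=3)
        epochs = assemble_dataset(simulate_dataset(cfg))
        table = build_feature_table(epochs, "overall")
        assert np.median(np.abs(table.X), axis=0).max() < 0.1

    def test_planted_correlations_recovered(self, study_epochs):
        """Mean per-epoch correlation within +/-0.05 of each planted target."""
        table = build_feature_table(study_epochs, "overall")
        for _, (i, j), r0, r1 in PLANTED_OVERALL:
            col = table.X[:, pair_to_index(i, j) - 1]
            assert col[table.labels == 0].mean() == pytest.approx(r0, abs=0.05)
            assert col[table.labels == 1].mean() == pytest.approx(r1, abs=0.05)

    def test_band_specific_planting(self):
        """A beta-band coupling shows up in the beta subband, not in delta."""
        from eegconn.wavelets import decompose_epochs

        recs = simulate_dataset(study_config(seed=5, band="beta"))
        epochs = assemble_dataset(recs)
        cache = decompose_epochs(epochs, bands=("delta", "beta"))
        tb = build_feature_table(epochs, "beta", band_cache=cache)
        td = build_feature_table(epochs, "delta", band_cache=cache)
        k = pair_to_index(9, 16) - 1  # O1-T6, planted 0.58 in group 1
        g1 = tb.labels == 1
        beta_r = tb.X[g1, k].mean()
        delta_r = td.X[g1, k].mean()
        assert beta_r - delta_r >= 0.2


class TestPinkNoise:
    def test_unit_variance(self, rng):
        x = pink_noise(30720, 512.0, rng)
        assert x.std() == pytest.approx(1.0, rel=1e-9)
        assert x.mean() == pytest.approx(0.0, abs=1e-9)

    def test_low_frequencies_dominate(self, rng):
        x = pink_noise(30720, 512.0, rng)
        spec = np.abs(np.fft.rfft(x)) ** 2
        f = np.fft.rfftfreq(30720, 1 / 512.0)
        low = spec[(f > 0.5) & (f < 10)].mean()
        high = spec[(f > 100) & (f < 200)].mean()
        assert low > 3 * high


def test_writer_round_trips(tmp_path, study_recordings):
    from eegconn.io import read_recordings

    write_dataset(study_recordings[:2], tmp_path)
    back = read_recordings(tmp_path)
    assert len(back) == 2
    for orig, rec in zip(study_recordings[:2], back):
        assert rec.subject_id == orig.subject_id
        assert rec.group == orig.group
        assert rec.fs == orig.fs
        np.testing.assert_allclose(rec.data, orig.data, rtol=1e-6, atol=1e-8)
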