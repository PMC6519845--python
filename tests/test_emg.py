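import numpy as np
import pytest
from scipy import stats

from emgcancel.emg import (EMGPair, MUAPLibrary, VolumeGeometry,
                           build_muap_library, cancellation_index,
                           cancellation_signal, synthesize_emg,
                           SilentRecordError)
from emgcancel.common_input import SignalTrace
from emgcancel.motoneuron import SpikeTrainSet

FS = 2048.0


def _pair_from_templates(templates, trains, duration):
    lib = MUAPLibrary(templates=[np.asarray(t, float) for t in templates],
                      fs=FS, innervation=np.ones(len(templates), int),
                      depths=np.full(len(templates), 5.0), library_id=1)
    spikes = SpikeTrainSet(trains=[np.asarray(t, float) for t in trains],
                           duration=duration)
    return synthesize_emg(spikes, lib)


class TestMuapLibrary:
    def test_amplitude_decays_with_depth(self):
        lib = build_muap_library(VolumeGeometry(), 100, 1, seed=0)
        p2p = np.array([t.max() - t.min() for t in lib.templates])
        # control innervation: normalize amplitude per fibre
        per_fiber = p2p / lib.innervation
        rho = stats.spearmanr(lib.depths, per_fiber).statistic
        assert rho < -0.8

    def test_amplitude_grows_with_innervation(self):
        lib = build_muap_library(VolumeGeometry(), 100, 2, seed=0)
        p2p = np.array([t.max() - t.min() for t in lib.templates])
        rho = stats.spearmanr(lib.innervation, np.log(p2p)).statistic
        assert rho > 0.3

    def test_innervation_range_printed(self):
        lib = build_muap_library(VolumeGeometry(), 100, 1, seed=1)
        assert lib.innervation.min() == 6
        assert lib.innervation.max() == 69

    def test_templates_zero_mean(self):
        lib = build_muap_library(VolumeGeometry(), 50, 3, seed=2)
        for t in lib.templates:
            assert abs(t.sum()) < 1e-6 * np.abs(t).sum()

    def test_libraries_distinct_and_reproducible(self):
        a = build_muap_library(VolumeGeometry(), 20, 1, seed=4)
        b = build_muap_library(VolumeGeometry(), 20, 1, seed=4)
        c = build_muap_library(VolumeGeometry(), 20, 2, seed=4)
        assert np.array_equal(a.templates[0], b.templates[0])
        assert not np.array_equal(a.templates[0], c.templates[0])

    def test_library_id_validated(self):
        with pytest.raises(ValueError):
            build_muap_library(VolumeGeometry(), 100, 16, seed=0)


class TestSynthesizeEmg:
    def test_single_spike_reproduces_template(self):
        tmpl = np.array([0.0, 1.0, -2.0, 1.0, 0.0])
        pair = _pair_from_templates([tmpl], [[100 / FS]], 0.5)
        n0 = 100
        assert np.allclose(pair.emg.samples[n0:n0 + 5], tmpl, atol=1e-12)
        assert np.allclose(pair.emg_nc.samples[n0:n0 + 5], np.abs(tmpl),
                           atol=1e-12)
        c = cancellation_signal(pair)
        assert np.allclose(c.samples, 0.0, atol=1e-12)

    def test_total_cancellation_of_opposite_templates(self):
        tmpl = np.array([0.5, 1.0, -1.5])
        pair = _pair_from_templates([tmpl, -tmpl],
                                    [[0.1], [0.1]], 0.5)
        assert np.allclose(pair.emg.samples, 0.0, atol=1e-12)
        assert pair.emg_nc.samples.max() > 0
        assert cancellation_index(pair) == pytest.approx(1.0)

    def test_pointwise_ordering_on_random_trains(self, rng):
        templates = [rng.standard_normal(40) for _ in range(12)]
        trains = [np.sort(rng.uniform(0, 4.0, size=rng.integers(5, 60)))
                  for _ in range(12)]
        pair = _pair_from_templates(templates, trains, 4.0)
        assert np.all(pair.emg_nc.samples >= np.abs(pair.emg.samples) - 1e-9)

    def test_linearity_in_spike_trains(self, rng):
        templates = [rng.standard_normal(30) for _ in range(4)]
        tr_a = [np.sort(rng.uniform(0, 2, 10)) for _ in range(4)]
        tr_b = [np.sort(rng.uniform(0, 2, 10)) for _ in range(4)]
        both = [np.sort(np.concatenate([a, b])) for a, b in zip(tr_a, tr_b)]
        p_a = _pair_from_templates(templates, tr_a, 2.0)
        p_b = _pair_from_templates(templates, tr_b, 2.0)
        p_ab = _pair_from_templates(templates, both, 2.0)
        assert np.allclose(p_ab.emg.samples,
                           p_a.emg.samples + p_b.emg.samples, atol=1e-9)
        assert np.allclose(p_ab.emg_nc.samples,
                           p_a.emg_nc.samples + p_b.emg_nc.samples, atol=1e-9)

    def test_unit_count_mismatch_rejected(self):
        tmpl = np.ones(5)
        with pytest.raises(ValueError):
            _pair_from_templates([tmpl, tmpl], [[0.1]], 1.0)


class TestCancellationIndex:
    def test_positive_templates_do_not_cancel(self, rng):
        templates = [np.abs(rng.standard_normal(20)) for _ in range(6)]
        trains = [np.sort(rng.uniform(0, 2, 40)) for _ in range(6)]
        pair = _pair_from_templates(templates, trains, 2.0)
        assert cancellation_index(pair) == pytest.approx(0.0, abs=1e-12)

    def test_grows_with_active_units(self, rng):
        templates = [rng.standard_normal(40) for _ in range(100)]
        trains = [np.sort(rng.uniform(0, 3, 30)) for _ in range(100)]
        cis = []
        for n in (1, 5, 20, 100):
            sub_tr = [t if i < n else np.empty(0)
                      for i, t in enumerate(trains)]
            pair = _pair_from_templates(templates, sub_tr, 3.0)
            cis.append(cancellation_index(pair))
        assert cis == sorted(cis)
        assert cis[-1] > 0.3

    def test_silent_record_raises(self):
        pair = _pair_from_templates([np.ones(4)], [[]], 1.0)
        with pytest.raises(SilentRecordError):
            cancellation_index(pair)

    def test_full_simulation_record_ordering(self, short_run):
        pair = short_run["pair"]
        assert np.all(pair.emg_nc.samples >= np.abs(pair.emg.samples) - 1e-9)
        assert 0.0 < cancellation_index(pair) < 1.0
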