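import numpy as np
import pytest

from emgcancel.common_input import (CommonInputSpec, generate_common_input,
                                    generate_noise_bank)
from emgcancel.motoneuron import (CumulativeSpikeTrain, SpikeTrainSet,
                                  build_pool, cumulative_spike_train,
                                  recruitment_summary, simulate_pool)

FS = 2048.0


def _run(pool, offset, g2=0.0, noise_gain=0.0, dur=3.0, seed=0):
    spec = CommonInputSpec(g2=g2, offset=offset, duration=dur, fs=FS)
    common = generate_common_input(spec, seed=seed)
    noise = generate_noise_bank(pool.n_units, dur, FS, noise_gain,
                                seed=seed + 1)
    return simulate_pool(pool, common, noise)


class TestBuildPool:
    def test_printed_resistance_endpoints(self, pool100):
        assert pool100.r_soma[0] == pytest.approx(1.15)
        assert pool100.r_soma[-1] == pytest.approx(0.65)
        assert pool100.r_dend[0] == pytest.approx(14.4)
        assert pool100.r_dend[-1] == pytest.approx(6.05)

    def test_low_index_units_have_lowest_threshold(self, pool100):
        g_in = pool100.input_conductance
        assert np.all(np.diff(g_in) > 0)  # rheobase grows with index

    def test_many_low_threshold_units(self, pool100):
        # exponential density: over half the pool lies in the lower third
        # of the input-conductance range
        g = pool100.input_conductance
        cut = g[0] + (g[-1] - g[0]) / 3.0
        assert np.mean(g < cut) > 0.5

    def test_single_unit_pool_is_low_threshold_end(self):
        p1 = build_pool(1)
        p100 = build_pool(100)
        assert p1.r_soma[0] == pytest.approx(p100.r_soma[0])

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            build_pool(0)


class TestSimulatePool:
    def test_zero_input_silent(self, pool100):
        spikes = _run(pool100, offset=0.0)
        assert spikes.total_spikes == 0

    def test_constant_suprathreshold_is_periodic(self, pool100):
        spikes = _run(pool100, offset=4.5e-3)
        st = spikes.trains[0]
        assert st.size > 5
        isi = np.diff(st[2:])  # after settling
        assert isi.std() / isi.mean() < 0.02

    def test_recruitment_monotone_in_offset(self, pool100):
        lo = _run(pool100, offset=3.5e-3, g2=5.7e-5, noise_gain=2.2e-4,
                  dur=4.0, seed=5)
        hi = _run(pool100, offset=4.3e-3, g2=5.7e-5, noise_gain=2.2e-4,
                  dur=4.0, seed=5)
        f_lo, r_lo = recruitment_summary(lo)
        f_hi, r_hi = recruitment_summary(hi)
        assert f_hi > f_lo
        assert r_hi > r_lo

    def test_smallest_units_fire_fastest(self, pool100):
        spikes = _run(pool100, offset=4.5e-3)
        rates = [st.size for st in spikes.trains]
        active = [r for r in rates if r > 0]
        assert rates[0] == max(rates)
        assert len(active) < 100  # partial recruitment

    def test_spike_trains_valid(self, short_run):
        spikes = short_run["spikes"]
        for st in spikes.trains:
            assert np.all(np.diff(st) > 4.9e-3)  # dead time floor
            if st.size:
                assert st[0] >= 0 and st[-1] <= spikes.duration

    def test_dt_guard(self, pool100, short_run):
        with pytest.raises(ValueError):
            simulate_pool(pool100, short_run["common"], short_run["noise"],
                          dt=0.2)


class TestCumulativeSpikeTrain:
    def test_conservation(self, short_run):
        cst = cumulative_spike_train(short_run["spikes"], FS)
        assert cst.total_spikes == short_run["spikes"].total_spikes

    def test_empty(self):
        spikes = SpikeTrainSet(trains=[np.empty(0)], duration=1.0)
        cst = cumulative_spike_train(spikes, FS)
        assert not cst.counts.any()

    def test_single_unit_two_spikes(self):
        spikes = SpikeTrainSet(trains=[np.array([0.5, 1.0])], duration=2.0)
        cst = cumulative_spike_train(spikes, 1000.0)
        nz = np.flatnonzero(cst.counts)
        assert list(nz) == [500, 1000]
        assert np.all(cst.counts[nz] == 1)

    def test_additivity_of_identical_units(self):
        st = np.array([0.1, 0.4, 0.9])
        one = cumulative_spike_train(
            SpikeTrainSet(trains=[st], duration=1.0), FS)
        two = cumulative_spike_train(
            SpikeTrainSet(trains=[st, st.copy()], duration=1.0), FS)
        assert np.array_equal(two.counts, 2 * one.counts)


class TestRecruitmentSummary:
    def test_no_spikes_flagged_as_zero(self):
        spikes = SpikeTrainSet(trains=[np.empty(0)] * 5, duration=2.0)
        frac, rate = recruitment_summary(spikes)
        assert frac == 0.0 and rate == 0.0

    def test_threshold_rate(self):
        spikes = SpikeTrainSet(
            trains=[np.arange(0, 2, 0.1), np.array([0.5])], duration=2.0)
        frac, rate = recruitment_summary(spikes, min_rate=1.0)
        assert frac == pytest.approx(0.5)
        assert rate == pytest.approx(10.0)
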