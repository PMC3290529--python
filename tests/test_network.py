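"""Network wiring: current assembly, relay fidelity, symmetries, controls."""

import numpy as np
import pytest

from spikemask.network import Network, NetworkConfig, assemble_current, run_network
from spikemask.neuron import SimulationClock, simulate_neuron
from spikemask.stimuli import build_schedule, make_fg_texture, make_uniform_mask


class TestAssembleCurrent:
    def test_zero_field_gives_zero_current(self):
        F = np.zeros((8, 8))
        assert (assemble_current([(F, 400.0, -700.0)], 8) == 0).all()

    def test_full_field_is_spatially_constant(self):
        # excitation 400 everywhere, inhibition -700 * (4096/4096): net -300
        F = np.ones((64, 64))
        I = assemble_current([(F, 400.0, -700.0)], 64)
        assert np.allclose(I, -300.0)

    def test_central_figure_geometry(self):
        feat1, _ = make_fg_texture(64, 16)
        I = assemble_current([(feat1.pixels, 400.0, -700.0)], 64)
        inside = feat1.pixels.astype(bool)
        # hand-evaluated: 400 - 700*(256/4096) inside, -700*(256/4096) outside
        assert np.allclose(I[inside], 356.25)
        assert np.allclose(I[~inside], -43.75)

    def test_shape_and_binarity_validated(self):
        with pytest.raises(ValueError):
            assemble_current([(np.ones((4, 8)), 1.0, 0.0)], 4)
        with pytest.raises(ValueError):
            assemble_current([(np.full((4, 4), 0.5), 1.0, 0.0)], 4)

    def test_inhibition_is_monotone_in_source_activity(self):
        """Growing an inhibitory source's active set can only lower currents."""
        small = np.zeros((8, 8))
        small[0, 0] = 1
        big = small.copy()
        big[0, 1] = 1
        I_small = assemble_current([(small, 0.0, -700.0)], 8)
        I_big = assemble_current([(big, 0.0, -700.0)], 8)
        assert (I_big <= I_small).all()


def small_fg_config(**kw):
    return NetworkConfig(N=8, mode="figure_ground", **kw)


class TestNetwork:
    def test_zero_input_network_stays_silent(self):
        cfg = small_fg_config()
        sched = build_schedule([], n_channels=2)
        raster = run_network(sched, cfg, SimulationClock(cfg.dt, 500))
        assert raster.data.sum() == 0

    def test_identical_runs_give_bit_identical_rasters(self):
        f1, f2 = make_fg_texture(8, 2)
        cfg = small_fg_config()
        sched = build_schedule([(0, f1, 0.0, 60.0), (1, f2, 0.0, 60.0)])
        clock = SimulationClock(cfg.dt, 400)
        a = run_network(sched, cfg, clock)
        b = run_network(sched, cfg, clock)
        assert np.array_equal(a.data, b.data)

    def test_layer1_matches_single_neuron_oracle(self):
        """Every layer-1 pixel is an independent neuron driven by w_input*F."""
        f1, f2 = make_fg_texture(8, 2)
        cfg = small_fg_config()
        n_steps = 500
        raster = run_network(
            build_schedule([(0, f1, 0.0, 100.0), (1, f2, 0.0, 100.0)]),
            cfg,
            SimulationClock(cfg.dt, n_steps),
        )
        trace = np.zeros(n_steps)
        trace[: int(100.0 / cfg.dt)] = cfg.w_input
        expected = simulate_neuron(trace, cfg.params, dt=cfg.dt)
        for i, j in [(3, 3), (4, 4)]:  # figure pixels of channel 0
            got = np.nonzero(raster.data[0, 0, :, i, j])[0]
            assert np.array_equal(got, expected)
        assert raster.data[0, 0, :, 0, 0].sum() == 0  # undriven background pixel

    def test_layer2_equals_delayed_relay_oracle_when_inhibition_off(self):
        """With w_inh=0 each layer-2 neuron is simulate_neuron driven by
        w_exc times its layer-1 twin's spike train, delayed one step."""
        cfg = NetworkConfig(N=4, mode="figure_ground", w_inh=0.0)
        f1, f2 = make_fg_texture(4, 2)
        n_steps = 400
        raster = run_network(
            build_schedule([(0, f1, 0.0, 60.0), (1, f2, 0.0, 60.0)]),
            cfg,
            SimulationClock(cfg.dt, n_steps),
        )
        for ch in (0, 1):
            for i in range(4):
                for j in range(4):
                    s1 = raster.data[ch, 0, :, i, j].astype(float)
                    I2 = np.zeros(n_steps)
                    I2[1:] = cfg.w_exc * s1[:-1]
                    expected = simulate_neuron(I2, cfg.params, dt=cfg.dt)
                    got = np.nonzero(raster.data[ch, 1, :, i, j])[0]
                    assert np.array_equal(got, expected), (ch, i, j)

    def test_raster_invariant_under_quarter_rotation(self):
        """All stimuli are 4-fold symmetric, so rasters must be too."""
        f1, f2 = make_fg_texture(8, 4)
        cfg = small_fg_config()
        raster = run_network(
            build_schedule([(0, f1, 0.0, 80.0), (1, f2, 0.0, 80.0)]),
            cfg,
            SimulationClock(cfg.dt, 500),
        )
        rotated = np.rot90(raster.data, k=1, axes=(3, 4))
        assert np.array_equal(raster.data, rotated)

    def test_channel_permutation_symmetry(self):
        """Swapping the channel inputs swaps the channel outputs (FG wiring)."""
        f1, f2 = make_fg_texture(8, 2)
        cfg = small_fg_config()
        clock = SimulationClock(cfg.dt, 500)
        fwd = run_network(build_schedule([(0, f1, 0.0, 80.0), (1, f2, 0.0, 80.0)]), cfg, clock)
        rev = run_network(build_schedule([(0, f2, 0.0, 80.0), (1, f1, 0.0, 80.0)]), cfg, clock)
        assert np.array_equal(fwd.data[0], rev.data[1])
        assert np.array_equal(fwd.data[1], rev.data[0])

    def test_uniform_drive_silences_layer2(self):
        """Full-field input: layer-2 current is 400-700 = -300, no early spikes."""
        um = make_uniform_mask(8)
        cfg = small_fg_config()
        raster = run_network(
            build_schedule([(0, um, 0.0, 60.0)], n_channels=2),
            cfg,
            SimulationClock(cfg.dt, 300),
        )
        assert raster.data[0, 0].sum() > 0  # layer 1 bursts
        assert raster.data[0, 1].sum() == 0  # layer 2 fully suppressed

    def test_on_off_mode_pools_both_channels(self):
        cfg = NetworkConfig(N=8, mode="on_off")
        assert cfg.layer2_sources(0) == (0, 1)
        assert small_fg_config().layer2_sources(0) == (0,)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(mode="lateral")
        with pytest.raises(ValueError):
            NetworkConfig(w_inh=5.0)

    def test_events_table_matches_raster_totals(self):
        f1, f2 = make_fg_texture(8, 2)
        raster = run_network(
            build_schedule([(0, f1, 0.0, 40.0), (1, f2, 0.0, 40.0)]),
            small_fg_config(),
            SimulationClock(0.2, 300),
        )
        events = raster.to_events()
        assert len(events) == raster.data.sum()
        assert set(events.columns) == {"t_ms", "channel", "layer", "row", "col"}
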