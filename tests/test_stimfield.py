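import math

import numpy as np
import pytest

from periax.morphology import build_morphology, segment_positions
from periax.stimfield import (
    ElectrodeConfig,
    PulseTrain,
    extracellular_potential,
    field_at_segments,
    load_field_map,
    make_pulse_train,
)


class TestPulseTrain:
    def test_100hz_10s_has_1000_pulses(self):
        cfg = PulseTrain(frequency=100.0, duration=10.0)
        assert cfg.n_pulses == 1000
        wave = make_pulse_train(cfg, dt=0.01)
        # count pulse onsets: zero -> nonzero transitions
        nz = wave != 0
        onsets = np.flatnonzero(nz[1:] & ~nz[:-1]) + 1
        if nz[0]:
            onsets = np.r_[0, onsets]
        assert onsets.size == 1000

    def test_charge_balance_per_pulse(self):
        cfg = PulseTrain(frequency=50.0, duration=0.2, amplitude=0.07)
        wave = make_pulse_train(cfg, dt=0.01)
        period = int(round(20.0 / 0.01))
        for k in range(cfg.n_pulses):
            assert wave[k * period:(k + 1) * period].sum() == pytest.approx(0.0)

    def test_first_phase_negative_by_default(self):
        wave = make_pulse_train(PulseTrain(duration=0.05), dt=0.01)
        first = wave[np.flatnonzero(wave)[0]]
        assert first < 0

    def test_phase_must_span_two_samples(self):
        with pytest.raises(ValueError, match="2\\*dt"):
            make_pulse_train(PulseTrain(phase_width=0.1), dt=0.06)

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PulseTrain(frequency=1000.0, phase_width=0.6)


class TestPotential:
    def test_hand_value_100um(self):
        # I/(4 pi sigma r) with I = 0.1 mA, sigma = 0.3 S/m, r = 100 um
        e = ElectrodeConfig(sigma=0.3)
        v = extracellular_potential(e, (100.0, 0.0, 0.0), 0.1)
        assert v == pytest.approx(265.3, abs=0.1)

    def test_inverse_r(self):
        e = ElectrodeConfig()
        v1 = extracellular_potential(e, (50.0, 0.0, 0.0), 1.0)
        v2 = extracellular_potential(e, (100.0, 0.0, 0.0), 1.0)
        assert v1 == pytest.approx(2 * v2)

    def test_decays_to_zero(self):
        e = ElectrodeConfig()
        assert extracellular_potential(e, (1e10, 0.0, 0.0), 1.0) == \
            pytest.approx(0.0, abs=1e-4)

    def test_linear_in_current(self):
        e = ElectrodeConfig()
        v = extracellular_potential(e, (77.0, 11.0, 5.0), 1.0)
        assert extracellular_potential(e, (77.0, 11.0, 5.0), -0.3) == \
            pytest.approx(-0.3 * v)

    def test_reciprocity(self):
        a, b = (12.0, -40.0, 9.0), (100.0, 55.0, -3.0)
        va = extracellular_potential(ElectrodeConfig(position=a), b, 1.0)
        vb = extracellular_potential(ElectrodeConfig(position=b), a, 1.0)
        assert va == pytest.approx(vb)

    def test_min_radius_clamp_warns(self):
        e = ElectrodeConfig(min_radius=5.0)
        with pytest.warns(RuntimeWarning, match="clamped"):
            v = extracellular_potential(e, (1.0, 0.0, 0.0), 1.0)
        v5 = extracellular_potential(e, (5.0, 0.0, 0.0), 1.0)
        assert v == pytest.approx(v5)

    def test_bipole_superposition(self):
        e = ElectrodeConfig(model="bipole", bipole_offset=200.0)
        mono = ElectrodeConfig()
        sink = ElectrodeConfig(position=(0.0, 0.0, 200.0))
        pt = (60.0, 10.0, 20.0)
        assert extracellular_potential(e, pt, 1.0) == pytest.approx(
            extracellular_potential(mono, pt, 1.0)
            - extracellular_potential(sink, pt, 1.0)
        )


class TestFieldMap:
    def test_scaling_with_distance(self, morph):
        e = ElectrodeConfig(position=(0.0, 1000.0, 0.0))
        near = field_at_segments(e, segment_positions(morph, (10.0, 0.0)))
        far = field_at_segments(e, segment_positions(morph, (100.0, 0.0)))
        nid = morph.node_ids[10]
        r_near = math.dist((10.0, morph.segments[nid].axial_position, 0.0),
                           e.position)
        r_far = math.dist((100.0, morph.segments[nid].axial_position, 0.0),
                          e.position)
        assert far.weights[nid] * r_far == pytest.approx(
            near.weights[nid] * r_near
        )

    def test_maximal_under_electrode(self, morph):
        y10 = morph.segments[morph.node_ids[10]].axial_position
        e = ElectrodeConfig(position=(0.0, y10, 0.0))
        fm = field_at_segments(e, segment_positions(morph, (20.0, 20.0)))
        node_w = {i: fm.weights[i] for i in morph.node_ids}
        assert max(node_w, key=node_w.get) == morph.node_ids[10]

    def test_grid_roundtrip_within_1pct(self, morph, tmp_path):
        import pandas as pd

        e = ElectrodeConfig(position=(0.0, 1000.0, 0.0))
        xs = np.arange(-20.0, 141.0, 10.0)
        ys = np.arange(-150.0, 2151.0, 25.0)
        zs = np.arange(-20.0, 141.0, 10.0)
        rows = [
            (x, y, z, extracellular_potential(e, (x, y, z), 1.0))
            for x in xs for y in ys for z in zs
        ]
        path = tmp_path / "grid.csv"
        pd.DataFrame(rows, columns=["x_um", "y_um", "z_um", "v_per_mA"]).to_csv(
            path, index=False
        )
        positions = segment_positions(morph, (55.0, 55.0))
        interp = load_field_map(path, positions)
        exact = field_at_segments(e, positions)
        for i in positions:
            assert interp.weights[i] == pytest.approx(
                exact.weights[i], rel=0.01
            )

    def test_constant_grid_constant_weights(self, morph, tmp_path):
        import pandas as pd

        xs = ys = zs = np.array([-3000.0, 0.0, 3000.0])
        rows = [(x, y, z, 7.5) for x in xs for y in ys for z in zs]
        path = tmp_path / "const.csv"
        pd.DataFrame(rows, columns=["x_um", "y_um", "z_um", "v_per_mA"]).to_csv(
            path, index=False
        )
        fm = load_field_map(path, segment_positions(morph, (10.0, 10.0)))
        assert set(np.round(list(fm.weights.values()), 12)) == {7.5}

    def test_out_of_bounds_names_compartment(self, morph, tmp_path):
        import pandas as pd

        xs = ys = zs = np.array([0.0, 10.0])
        rows = [(x, y, z, 1.0) for x in xs for y in ys for z in zs]
        path = tmp_path / "small.csv"
        pd.DataFrame(rows, columns=["x_um", "y_um", "z_um", "v_per_mA"]).to_csv(
            path, index=False
        )
        with pytest.raises(ValueError, match="compartment"):
            load_field_map(path, segment_positions(morph, (5.0, 5.0)))
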