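"""Tissue model, blood optics and absorption mixing."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ppgmc
from ppgmc.optics import (
    BloodOpticalProperties,
    LayerSpec,
    OpticalProperties,
    PerfusionState,
    TissueModel,
    mixed_absorption,
    resolve_layer_properties,
    solve_baseline_absorption,
)


class TestMixedAbsorption:
    @pytest.mark.parametrize(
        "base,V,sto2,hbo,hb,expected",
        [
            (0.03, 0.0, 0.95, 0.5, 0.9, 0.03),  # no blood -> baseline
            (0.7, 1.0, 1.0, 0.2, 0.4, 0.2),  # pure oxygenated blood
            (0.02, 0.5, 0.5, 0.2, 0.4, 0.16),  # hand-evaluated mix
        ],
    )
    def test_values(self, base, V, sto2, hbo, hb, expected):
        assert mixed_absorption(base, V, sto2, hbo, hb) == pytest.approx(expected)

    @pytest.mark.parametrize("V,sto2", [(-0.1, 0.5), (1.1, 0.5), (0.5, -0.1), (0.5, 1.2)])
    def test_domain_errors(self, V, sto2):
        with pytest.raises(ValueError):
            mixed_absorption(0.03, V, sto2, 0.2, 0.4)

    @given(
        base=st.floats(0, 1),
        sto2=st.floats(0, 1),
        hbo=st.floats(0, 2),
        hb=st.floats(0, 2),
    )
    @settings(deadline=None, max_examples=50)
    def test_linear_in_blood_volume(self, base, sto2, hbo, hb):
        """Finite differences of V at fixed StO2 are constant (linearity)."""
        f = [mixed_absorption(base, v, sto2, hbo, hb) for v in (0.0, 0.25, 0.5)]
        assert f[1] - f[0] == pytest.approx(f[2] - f[1], abs=1e-12)

    @given(V=st.floats(0, 1), base=st.floats(0, 1))
    @settings(deadline=None, max_examples=50)
    def test_linear_and_monotone_in_sto2(self, V, base):
        """At fixed V, mu_a moves linearly from the Hb to the HbO value."""
        hbo, hb = 0.2, 0.4  # deoxy absorbs more (red-light regime)
        f = [mixed_absorption(base, V, s, hbo, hb) for s in (0.0, 0.5, 1.0)]
        assert f[1] - f[0] == pytest.approx(f[2] - f[1], abs=1e-12)
        assert f[0] >= f[1] >= f[2]  # decreasing when hb > hbo

    def test_partial_derivative_signs(self):
        """mu_a grows with each blood coefficient (at V, StO2 > 0)."""
        lo = mixed_absorption(0.03, 0.3, 0.6, 0.2, 0.4)
        assert mixed_absorption(0.03, 0.3, 0.6, 0.25, 0.4) > lo
        assert mixed_absorption(0.03, 0.3, 0.6, 0.2, 0.45) > lo

    def test_baseline_roundtrip(self):
        base = solve_baseline_absorption(0.039, 0.04, 0.95, 0.171, 1.728)
        assert mixed_absorption(base, 0.04, 0.95, 0.171, 1.728) == pytest.approx(
            0.039, rel=1e-12
        )


class TestBuiltinModel:
    def test_layer_stack(self, buccal_model):
        assert [lay.name for lay in buccal_model.layers] == [
            "mucosa",
            "submucosa",
            "muscle",
        ]
        assert buccal_model.layers[1].perfused
        # bounded simulation volume by default; semi-infinite available
        assert buccal_model.layers[-1].thickness == pytest.approx(0.15)
        unbounded = ppgmc.builtin_buccal_model(muscle_thickness=None)
        assert unbounded.layers[-1].thickness is None

    def test_tabulated_values(self, buccal_model):
        muscle = buccal_model.layers[2]
        assert muscle.properties[660.0].mu_a == 0.28
        assert muscle.properties[880.0].mu_a == 0.18
        sub = buccal_model.layers[1]
        assert sub.blood_volume_fraction == 0.04
        assert sub.properties[880.0].g == 0.956
        mucosa = buccal_model.layers[0]
        assert mucosa.blood_volume_fraction == 0.08
        assert mucosa.properties[660.0].mu_s == 26.33

    def test_resolve_reproduces_composites_at_nominal(self, buccal_model, blood, nominal):
        """At the nominal perfusion state the resolved stack equals the table."""
        for wl in (660.0, 880.0):
            props = resolve_layer_properties(buccal_model, wl, nominal, blood)
            for lay, got in zip(buccal_model.layers, props):
                ref = lay.properties[wl]
                assert got.mu_a == pytest.approx(ref.mu_a, rel=1e-12)
                assert (got.mu_s, got.g, got.n) == (ref.mu_s, ref.g, ref.n)

    def test_resolve_at_880_nominal(self, buccal_model, blood, nominal):
        props = resolve_layer_properties(buccal_model, 880.0, nominal, blood)
        assert props[0].mu_a == pytest.approx(0.026)
        assert props[0].mu_s == pytest.approx(22.05)

    def test_bloodless_submucosa_uses_baseline(self, buccal_model, blood):
        """V = 0 strips the blood contribution from the submucosa."""
        props = resolve_layer_properties(
            buccal_model, 660.0, PerfusionState(blood_volume=0.0, sto2=0.95), blood
        )
        base = solve_baseline_absorption(0.039, 0.04, 0.95, blood.mu_a_hbo[660.0], blood.mu_a_hb[660.0])
        assert props[1].mu_a == pytest.approx(base, rel=1e-12)
        assert props[1].mu_a < 0.039

    def test_missing_wavelength_errors(self, buccal_model, blood, nominal):
        with pytest.raises(KeyError):
            resolve_layer_properties(buccal_model, 532.0, nominal, blood)


class TestValidation:
    def test_optical_properties_invariants(self):
        with pytest.raises(ValueError):
            OpticalProperties(mu_a=-0.1, mu_s=1.0, g=0.9, n=1.4)
        with pytest.raises(ValueError):
            OpticalProperties(mu_a=0.0, mu_s=0.0, g=0.9, n=1.4)
        with pytest.raises(ValueError):
            OpticalProperties(mu_a=0.1, mu_s=1.0, g=1.5, n=1.4)
        with pytest.raises(ValueError):
            OpticalProperties(mu_a=0.1, mu_s=1.0, g=0.9, n=0.9)

    def test_only_deepest_layer_unbounded(self):
        p = {660.0: OpticalProperties(0.1, 1.0, 0.9, 1.4)}
        with pytest.raises(ValueError):
            TissueModel(
                layers=[
                    LayerSpec("a", None, p),
                    LayerSpec("b", 1.0, p),
                ]
            )

    def test_perfusion_state_bounds(self):
        with pytest.raises(ValueError):
            PerfusionState(blood_volume=1.2)
        with pytest.raises(ValueError):
            PerfusionState(sto2=-0.1)

    def test_blood_table_wavelength_mismatch(self):
        with pytest.raises(ValueError):
            BloodOpticalProperties(mu_a_hbo={660.0: 0.1}, mu_a_hb={880.0: 0.2})


class TestConfigIO:
    def test_yaml_roundtrip(self, tmp_path, buccal_model):
        path = tmp_path / "model.yaml"
        buccal_model.to_yaml(path)
        back = ppgmc.TissueModel.from_yaml(path)
        assert [l.name for l in back.layers] == [l.name for l in buccal_model.layers]
        for a, b in zip(back.layers, buccal_model.layers):
            assert a.thickness == b.thickness
            assert a.perfused == b.perfused
            assert a.properties == b.properties

    def test_blood_csv_roundtrip(self, tmp_path, blood):
        path = tmp_path / "blood.csv"
        path.write_text(
            "wavelength_nm,mu_a_hbo_mm,mu_a_hb_mm\n660,0.171,1.728\n880,0.650,0.395\n"
        )
        loaded = BloodOpticalProperties.from_csv(path)
        assert loaded.mu_a_hbo == blood.mu_a_hbo
        assert loaded.mu_a_hb == blood.mu_a_hb

    def test_model_interfaces(self, buccal_model):
        tops = buccal_model.interfaces()
        assert tops[0] == 0.0
        assert tops == sorted(tops)
        assert len(tops) == 3
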