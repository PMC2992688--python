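"""Defaults, invariants and the override-config dialect."""

import pytest
from hypothesis import given, settings, strategies as st

import loxsim as lx
from loxsim.parameters import ENZYME_IDS, ISOMERS, LOX_ISOZYMES


class TestDefaults:
    def test_published_kinetic_constants(self, default_config):
        """Spot-check the embedded table in the nmol/mL unit system."""
        k = default_config.kinetics
        assert k["L2"].vmax_scaled == pytest.approx(39_000.0)
        assert k["L1"].km == pytest.approx(490_000.0)
        assert k["HPL_SZE"].vmax_scaled == pytest.approx(285_000.0)
        assert k["HPL_RZE"].vmax_scaled == pytest.approx(38_500.0)
        assert k["HPL_SZE"].km == pytest.approx(50_000.0)
        assert default_config.initial_la == pytest.approx(67.0)
        assert default_config.duration == pytest.approx(100.0)
        assert default_config.genotype == lx.WILD_TYPE

    @pytest.mark.parametrize("enzyme", ENZYME_IDS)
    def test_vmax_scaling_consistent(self, default_config, enzyme):
        """vmax_scaled / vmax_specific equals the 15 mg/mL protein
        reference to within the 2% rounding of the printed values."""
        k = default_config.kinetics[enzyme]
        assert k.vmax_scaled / k.vmax_specific == pytest.approx(15.0, rel=0.02)

    @pytest.mark.parametrize("isozyme", LOX_ISOZYMES)
    def test_ratio_rows_sum_to_one(self, default_config, isozyme):
        total = default_config.ratios.row_sum(isozyme)
        assert abs(total - 1.0) <= 0.005
        # and the normalized rows are exact
        assert sum(default_config.ratios.normalized(isozyme).values()) == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_branching_fraction_spot_value(self, default_config):
        assert default_config.ratios.fraction["L3"]["13HOD_SZE"] == (
            pytest.approx(0.068)
        )

    def test_kinetics_frame_layout(self):
        df = lx.kinetics_frame()
        assert list(df.columns) == ["enzyme_id", "km", "vmax_specific", "vmax_scaled"]
        assert len(df) == 5


class TestGenotype:
    @pytest.mark.parametrize(
        "name,present",
        [
            ("L123", {"L1", "L2", "L3"}),
            ("L13", {"L1", "L3"}),
            ("L2", {"L2"}),
            ("L0", set()),
        ],
    )
    def test_name_subset_bijection(self, name, present):
        g = lx.Genotype.from_name(name)
        assert g.present == frozenset(present)
        assert g.name == name

    @pytest.mark.parametrize("bad", ["", "L", "L4", "L11", "X12", "L321x"])
    def test_invalid_names_rejected(self, bad):
        with pytest.raises(lx.ConfigError):
            lx.Genotype.from_name(bad)


class TestConfigDialect:
    def test_empty_config_is_identity(self, default_config):
        assert lx.loads_config("") == default_config

    def test_round_trip(self, default_config):
        assert lx.loads_config(lx.dump_config(default_config)) == default_config

    def test_single_key_override(self, default_config):
        cfg = lx.loads_config("duration: 60")
        assert cfg.duration == 60.0
        assert cfg.kinetics == default_config.kinetics
        assert cfg.initial_la == default_config.initial_la

    def test_dotted_kinetics_override(self):
        cfg = lx.loads_config("kinetics.L1.km: 980000.0")
        assert cfg.kinetics["L1"].km == pytest.approx(980_000.0)
        assert cfg.kinetics["L2"].km == pytest.approx(490_000.0)

    def test_genotype_override(self):
        assert lx.loads_config("genotype: L13").genotype.name == "L13"

    @pytest.mark.parametrize(
        "text",
        [
            "kinetics.L1.km: -1",
            "initial_la: -5",
            "duration: 0",
            "unknown_key: 1",
            "kinetics.L9.km: 1",
            "ratios.L1.13HOD_SZE: 1.5",
        ],
    )
    def test_invalid_values_rejected(self, text):
        with pytest.raises(lx.ConfigError):
            lx.loads_config(text)

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            lx.load_config(tmp_path / "nope.yaml")

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        duration=st.floats(1.0, 500.0, allow_nan=False),
        la0=st.floats(1.0, 1000.0, allow_nan=False),
        km=st.floats(1e3, 1e7, allow_nan=False),
    )
    def test_round_trip_with_overrides(self, duration, la0, km):
        """Serialize/reload is the identity for arbitrary valid overrides."""
        text = (
            f"duration: {duration!r}\n"
            f"initial_la: {la0!r}\n"
            f"kinetics.L2.km: {km!r}\n"
        )
        cfg = lx.loads_config(text)
        assert lx.loads_config(lx.dump_config(cfg)) == cfg


class TestScaling:
    def test_with_km_scaled(self, default_config):
        cfg = default_config.with_km_scaled("L3", 0.001)
        assert cfg.kinetics["L3"].km == pytest.approx(490.0)
        assert cfg.kinetics["L3"].vmax_scaled == pytest.approx(2550.0)

    def test_with_vmax_scaled(self, default_config):
        cfg = default_config.with_vmax_scaled("L2", 0.0)
        assert cfg.kinetics["L2"].vmax_scaled == 0.0
        assert cfg.kinetics["L2"].vmax_specific == 0.0
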