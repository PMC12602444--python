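"""Tracer mass balance: tissue masses, plant pools, pool construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mycoflux as mf
from mycoflux.massbalance import (
    MassBalanceError,
    MissingControlError,
    PoolKind,
    plant_pool,
    tissue_tracer_mass,
)
from mycoflux.units import Element, EnrichmentFlag


class TestTissueTracerMass:
    # hand-arithmetic oracle: ape x content x biomass x 1e6
    @pytest.mark.parametrize(
        "ape, content, biomass, expected",
        [
            (0.01, 0.02, 1.0, 200.0),
            (0.0, 0.45, 3.0, 0.0),
            (0.005, 0.45, 2.0, 4500.0),
        ],
    )
    def test_known_values(self, ape, content, biomass, expected):
        assert tissue_tracer_mass(ape, content, biomass) == pytest.approx(
            expected, rel=1e-12
        )

    def test_rejects_nonpositive_biomass(self):
        with pytest.raises(MassBalanceError):
            tissue_tracer_mass(0.01, 0.5, 0.0)

    def test_rejects_content_outside_unit_interval(self):
        with pytest.raises(MassBalanceError):
            tissue_tracer_mass(0.01, 1.2, 1.0)

    @given(
        st.floats(-0.05, 0.5),
        st.floats(0.001, 0.99),
        st.floats(0.01, 50),
    )
    def test_linearity_in_each_argument(self, ape, content, biomass):
        base = tissue_tracer_mass(ape, content, biomass)
        assert tissue_tracer_mass(ape, content, 2 * biomass) == pytest.approx(
            2 * base, rel=1e-9, abs=1e-12
        )
        assert tissue_tracer_mass(2 * ape, content, biomass) == pytest.approx(
            2 * base, rel=1e-9, abs=1e-12
        )

    def test_percent_inputs_divided_by_100_match_fractions(self):
        frac = tissue_tracer_mass(0.0025, 0.45, 2.0)
        pct = tissue_tracer_mass(0.25 / 100, 45.0 / 100, 2.0)
        assert pct == pytest.approx(frac, rel=1e-12)


class TestPlantPool:
    def _pool(self, tissues):
        return plant_pool(
            Element.N15, PoolKind.RECEIVED, "L1", "orchid sp.", "orchid", tissues
        )

    def test_sums_tissues_and_keeps_breakdown(self):
        pool = self._pool(
            [
                ("aboveground", 150.0, EnrichmentFlag.OK),
                ("belowground", 50.0, EnrichmentFlag.OK),
            ]
        )
        assert pool.mass_ug == pytest.approx(200.0)
        assert pool.tissue_breakdown == {"aboveground": 150.0, "belowground": 50.0}

    def test_single_tissue_total_is_that_tissue(self):
        pool = self._pool([("belowground", 42.0, EnrichmentFlag.OK)])
        assert pool.mass_ug == pytest.approx(42.0)

    def test_negative_tissue_flag_propagates(self):
        pool = self._pool(
            [
                ("aboveground", 120.0, EnrichmentFlag.OK),
                ("belowground", -5.0, EnrichmentFlag.BELOW_ZERO),
            ]
        )
        assert pool.mass_ug == pytest.approx(115.0)
        assert pool.flag is EnrichmentFlag.BELOW_ZERO

    def test_duplicate_tissue_raises(self):
        with pytest.raises(MassBalanceError):
            self._pool(
                [
                    ("aboveground", 1.0, EnrichmentFlag.OK),
                    ("aboveground", 2.0, EnrichmentFlag.OK),
                ]
            )

    def test_permutation_invariant(self):
        tissues = [
            ("aboveground", 11.0, EnrichmentFlag.OK),
            ("belowground", 29.0, EnrichmentFlag.OK),
        ]
        assert self._pool(tissues).mass_ug == self._pool(tissues[::-1]).mass_ug


class TestBuildPools:
    def test_four_pools_per_labelled_microcosm(self, noise_free_run):
        _, measurements, _ = noise_free_run
        pools = mf.build_pools(measurements)
        one = pools[pools["microcosm_id"] == "L1"]
        assert len(one) == 4  # 2 elements x (donor + recipient)
        kinds = one.groupby("element")["pool_kind"].apply(set)
        for element in ("13C", "15N"):
            assert kinds[element] == {
                PoolKind.ASSIMILATED.value,
                PoolKind.RECEIVED.value,
            }

    def test_reciprocal_orientations_swap_donor_roles(self, noise_free_run):
        cfg, measurements, _ = noise_free_run
        pools = mf.build_pools(measurements)
        donors = pools[pools["pool_kind"] == PoolKind.ASSIMILATED.value]
        # orientation A: orchid is the 13C donor; orientation B: pine is
        a_donor = donors[
            (donors["microcosm_id"] == "L1") & (donors["element"] == "13C")
        ]["plant_role"].iloc[0]
        b_donor = donors[
            (donors["microcosm_id"] == f"L{cfg.n_labelled + 1}")
            & (donors["element"] == "13C")
        ]["plant_role"].iloc[0]
        assert (a_donor, b_donor) == ("orchid", "pine")

    def test_controls_emit_no_pools(self, noise_free_run):
        _, measurements, _ = noise_free_run
        pools = mf.build_pools(measurements)
        assert not pools["microcosm_id"].str.startswith("K").any()

    def test_pool_mass_equals_tissue_sum(self, noise_free_run):
        _, measurements, _ = noise_free_run
        pools = mf.build_pools(measurements)
        np.testing.assert_allclose(
            pools["mass_ug"],
            pools["aboveground_ug"] + pools["belowground_ug"],
            rtol=1e-12,
        )

    def test_missing_control_raises_actionable_error(self, noise_free_run):
        _, measurements, _ = noise_free_run
        no_controls = measurements[measurements["treatment"] == "labelled"]
        with pytest.raises(MissingControlError):
            mf.build_pools(no_controls)

    def test_control_baselines_pooled_per_species_tissue(self, noise_free_run):
        _, measurements, _ = noise_free_run
        baselines = mf.control_baselines(measurements)
        # 2 species x 2 tissues x 2 elements
        assert len(baselines) == 8
        assert (baselines["n_control"] == 4).all()
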