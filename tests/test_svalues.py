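"""Cellular S values: quadrature engine vs closed properties and MC oracle."""

import numpy as np
import pytest

from celldose.nuclide import ElectronEmissionSpectrum, build_dpk
from celldose.packing import RadiiDistribution, build_assembly
from celldose.svalues import (
    CellGeometry,
    KernelMoments,
    s_cross_pair,
    s_cross_pair_mc,
    s_value_mc,
    s_value_single_cell,
    s_values_in_assembly,
)

MDA = CellGeometry(9.45, 6.65)


def test_geometry_validation():
    with pytest.raises(ValueError):
        CellGeometry(5.0, 6.0)


def test_proximity_ordering(kernel, moments):
    s = s_value_single_cell(MDA, kernel, moments=moments)
    assert s.S_NN > s.S_NCy > s.S_NCs > 0


def test_short_range_emitter_gives_zero_surface_svalue(constant_stopping_table):
    # max range 1 um < R_c - R_n = 2.8 um: no surface decay reaches the nucleus
    sp = ElectronEmissionSpectrum.from_lines([(1.0, 5.0)])
    k = build_dpk(sp, constant_stopping_table)
    s = s_value_single_cell(MDA, k)
    assert s.S_NCs == 0.0
    assert s.S_NN > 0


def test_nuclear_svalue_decreases_with_nucleus_radius(kernel, moments):
    vals = [s_value_single_cell(CellGeometry(12.0, rn), kernel,
                                moments=moments).S_NN
            for rn in (4.0, 6.0, 8.0, 10.0)]
    assert np.all(np.diff(vals) < 0)


def test_surface_svalue_decreases_with_cell_radius(kernel, moments):
    vals = [s_value_single_cell(CellGeometry(rc, 5.0), kernel,
                                moments=moments).S_NCs
            for rc in (7.0, 9.0, 12.0, 15.0)]
    assert np.all(np.diff(vals) < 0)


def test_quadrature_matches_mc_oracle(kernel, moments, spectrum, water):
    rng = np.random.default_rng(7)
    for _ in range(3):
        rc = rng.uniform(8.0, 12.0)
        rn = rng.uniform(0.45, 0.8) * rc
        geom = CellGeometry(rc, rn)
        s = s_value_single_cell(geom, kernel, moments=moments)
        for region in ("N", "Cy", "Cs"):
            mc = s_value_mc(spectrum, water, geom, region, geom.R_n,
                            n_samples=200_000, rng=rng)
            assert s[region] == pytest.approx(mc, rel=0.02)


class TestCrossPair:
    def test_zero_beyond_support(self, kernel, moments):
        L = kernel.r_max_um + MDA.R_c + MDA.R_n + 1.0
        assert s_cross_pair(MDA, MDA, L, "Cs", kernel, moments=moments) == \
            pytest.approx(0.0, abs=1e-18)

    def test_coincidence_limit_recovers_self_svalue(self, kernel, moments):
        s_self = s_value_single_cell(MDA, kernel, moments=moments)
        s0 = s_cross_pair(MDA, MDA, 0.0, "N", kernel, moments=moments)
        assert s0 == pytest.approx(s_self.S_NN, rel=0.01)

    def test_contact_pair_vs_mc_oracle(self, kernel, moments, spectrum, water):
        L = 2 * MDA.R_c
        for region in ("Cs", "N"):
            quad = s_cross_pair(MDA, MDA, L, region, kernel, moments=moments)
            mc = s_cross_pair_mc(MDA, MDA, L, region, spectrum, water,
                                 n_samples=400_000, rng=3)
            assert quad == pytest.approx(mc, rel=0.05)

    def test_reciprocity_for_identical_cells(self, kernel, moments):
        a = CellGeometry(10.0, 7.0)
        fwd = s_cross_pair(a, a, 21.0, "N", kernel, moments=moments)
        rev = s_cross_pair(a, a, 21.0, "N", kernel, moments=moments)
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_negative_distance_rejected(self, kernel):
        with pytest.raises(ValueError):
            s_cross_pair(MDA, MDA, -1.0, "N", kernel)


class TestAssembly:
    def test_single_cell_assembly_matches_single_cell(self, kernel, moments):
        dist = RadiiDistribution(9.45, 0.0, 6.65, 0.0)
        model = build_assembly(dist, 1, seed=5)
        asm = s_values_in_assembly(model, kernel, moments=moments)
        ref = s_value_single_cell(CellGeometry(9.45, 6.65), kernel,
                                  moments=moments)
        assert asm.self_NN[0] == pytest.approx(ref.S_NN, rel=0.005)
        assert asm.cross_NN[0] == 0.0
        assert asm.effective("Cy")[0] == pytest.approx(ref.S_NCy, rel=0.005)

    def test_cross_totals_match_direct_pairwise_sum(self, kernel, moments):
        dist = RadiiDistribution(9.45, 1.0, 6.65, 0.8)
        model = build_assembly(dist, 20, seed=9)
        asm = s_values_in_assembly(model, kernel, moments=moments)
        geoms = [CellGeometry(rc, rn) for rc, rn in zip(model.R_c, model.R_n)]
        for i in (0, 7, 13):
            direct = 0.0
            for j in range(model.n_cells):
                if j == i:
                    continue
                L = float(np.linalg.norm(model.centers[i] - model.centers[j]))
                direct += s_cross_pair(geoms[j], geoms[i], L, "Cy", kernel,
                                       moments=moments)
            assert asm.cross_NCy[i] == pytest.approx(direct, rel=0.02)

    def test_cluster_crossfire_raises_cytoplasm_svalue(self, small_cluster,
                                                       kernel, moments):
        _, asm = small_cluster
        single = s_value_single_cell(MDA, kernel, moments=moments)
        assert asm.effective("Cy").mean() > 1.2 * single.S_NCy
        assert np.all(asm.cross_NN >= 0)

    def test_decomposition_total_equals_self_plus_cross(self, small_cluster):
        model, asm = small_cluster
        from celldose.kinetics import assign_activity
        from celldose.radiobiology import per_cell_dose

        amap = assign_activity(model, {"N": 100.0, "Cy": 50.0, "Cs": 50.0},
                               "uniform")
        dose = per_cell_dose(amap, asm)
        assert np.allclose(dose.total, dose.self_dose + dose.cross)
        assert np.all(dose.cross >= 0)
        expected_self = (100.0 * asm.self_NN + 50.0 * asm.self_NCy
                         + 50.0 * asm.self_NCs)
        assert np.allclose(dose.self_dose, expected_self)
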