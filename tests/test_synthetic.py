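"""Synthetic inputs and the bundled benchmark-scenario registry."""

import numpy as np
import pytest

from celldose.kinetics import cumulated_activity
from celldose.synthetic import (
    SyntheticUptakeSpec,
    available_scenarios,
    generate_timecourse,
    load_scenario,
)


class TestTimecourse:
    def test_noiseless_linear_recovers_closed_form(self):
        spec = SyntheticUptakeSpec(plateaus_Bq={"N": 0.05, "Cy": 0.1, "Cs": 0.1},
                                   sampling_times_h=(6.0, 12.0, 24.0),
                                   shape="linear", t_plateau_h=24.0)
        curves = generate_timecourse(spec)
        # linear ramp to plateau A over T: cumulated = A T / 2
        assert cumulated_activity(curves["N"], 24.0) == \
            pytest.approx(0.05 * 24.0 / 2.0 * 3600.0, rel=1e-12)

    def test_zero_plateaus_give_zero_curves(self):
        spec = SyntheticUptakeSpec(plateaus_Bq={"N": 0.0, "Cy": 0.0, "Cs": 0.0})
        curves = generate_timecourse(spec)
        for c in curves.values():
            assert np.all(c.activities_Bq == 0.0)

    def test_compartments_sum_to_whole_cell(self):
        spec = SyntheticUptakeSpec(plateaus_Bq={"N": 0.03, "Cy": 0.2, "Cs": 0.1},
                                   shape="saturating", noise_cv=0.05, seed=3)
        curves = generate_timecourse(spec)
        total = sum(curves[c].activities_Bq for c in ("N", "Cy", "Cs"))
        assert np.allclose(curves["cell"].activities_Bq, total)

    def test_deterministic_given_seed(self):
        spec = SyntheticUptakeSpec(plateaus_Bq={"N": 0.05, "Cy": 0.1, "Cs": 0.1},
                                   noise_cv=0.2, seed=42)
        a = generate_timecourse(spec)
        b = generate_timecourse(spec)
        assert np.array_equal(a["N"].activities_Bq, b["N"].activities_Bq)

    def test_noise_replicates_center_on_truth(self):
        truth = SyntheticUptakeSpec(plateaus_Bq={"N": 0.05, "Cy": 0.1, "Cs": 0.1})
        ref = cumulated_activity(generate_timecourse(truth)["N"], 24.0)
        vals = []
        for seed in range(100):
            spec = SyntheticUptakeSpec(
                plateaus_Bq={"N": 0.05, "Cy": 0.1, "Cs": 0.1},
                noise_cv=0.1, seed=seed)
            vals.append(cumulated_activity(generate_timecourse(spec)["N"], 24.0))
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - ref) < 3 * se

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticUptakeSpec(plateaus_Bq={"N": -1.0})
        with pytest.raises(ValueError):
            SyntheticUptakeSpec(plateaus_Bq={"N": 1.0}, shape="step")


# hand-audited benchmark table: (whole-cell, nuclear) cumulated activity in
# Bq s, plus the observed spatial pattern of each exposure
REFERENCE = {
    "MDA-468/EGF/1h": (331, 72, "peripheral"),
    "MDA-468/EGF/24h": (19558, 3688, "uniform"),
    "SQ20B/EGF/1h": (242, 42, "peripheral"),
    "SQ20B/EGF/24h": (15594, 1597, "peripheral"),
    "231-H2N/EGF/1h": (13, 2, "uniform"),
    "231-H2N/EGF/24h": (1533, 108, "uniform"),
    "MDA-468/Tz/1h": (10, 1, "uniform"),
    "MDA-468/Tz/24h": (1026, 67, "uniform"),
    "SQ20B/Tz/1h": (14, 2, "uniform"),
    "SQ20B/Tz/24h": (1274, 170, "uniform"),
    "231-H2N/Tz/1h": (96, 46, "peripheral"),
    "231-H2N/Tz/24h": (5947, 1884, "uniform"),
}

RADII = {"MDA-468": (9.45, 1.71, 6.65, 1.30),
         "SQ20B": (10.61, 1.24, 8.10, 1.39),
         "231-H2N": (11.21, 2.59, 7.09, 1.44)}

ALPHA_BETA = {"MDA-468": (0.46, 0.003), "SQ20B": (0.20, 0.001),
              "231-H2N": (0.12, 0.06)}


class TestScenarioRegistry:
    @pytest.mark.parametrize("name", sorted(REFERENCE))
    def test_fixture_integrity(self, name):
        cell, nuc, spatial = REFERENCE[name]
        scn = load_scenario(name)
        assert scn.acum_cell == cell
        assert scn.acum_nucleus == nuc
        assert scn.spatial == spatial
        rc, sdc, rn, sdn = RADII[scn.cell_line.name]
        assert (scn.cell_line.radii.mean_Rc, scn.cell_line.radii.sd_Rc) == (rc, sdc)
        assert (scn.cell_line.radii.mean_Rn, scn.cell_line.radii.sd_Rn) == (rn, sdn)
        assert (scn.cell_line.alpha, scn.cell_line.beta) == ALPHA_BETA[scn.cell_line.name]

    def test_triple_splits_nonnuclear_evenly(self):
        scn = load_scenario("MDA-468/EGF/1h")
        triple = scn.triple
        assert triple["N"] == 72.0
        assert triple["Cy"] == triple["Cs"] == pytest.approx(129.5)

    def test_unknown_scenario_lists_available(self):
        with pytest.raises(KeyError, match="available"):
            load_scenario("HeLa/EGF/1h")
        assert len(available_scenarios()) == 12


def test_end_to_end_smoke_from_synthetic_inputs():
    """Synthetic curves -> cumulated activity -> dose -> SF runs standalone."""
    from celldose.kinetics import assign_activity, split_nonnuclear
    from celldose.packing import RadiiDistribution, build_assembly
    from celldose.pipeline import reference_kernel
    from celldose.radiobiology import (RadiosensitivityParams,
                                       per_cell_dose, population_outcomes,
                                       survival_probability)
    from celldose.svalues import s_values_in_assembly

    spec = SyntheticUptakeSpec(plateaus_Bq={"N": 0.05, "Cy": 0.08, "Cs": 0.08},
                               noise_cv=0.05, seed=17)
    curves = generate_timecourse(spec)
    acum_cell = cumulated_activity(curves["cell"], 24.0)
    acum_nuc = cumulated_activity(curves["N"], 24.0)
    triple = split_nonnuclear(acum_cell, acum_nuc)
    model = build_assembly(RadiiDistribution(9.45, 1.71, 6.65, 1.30), 60, seed=2)
    kernel, moments = reference_kernel()
    asm = s_values_in_assembly(model, kernel, moments=moments)
    amap = assign_activity(model, triple, "uniform")
    dose = per_cell_dose(amap, asm)
    sp = survival_probability(dose, RadiosensitivityParams(0.46, 0.003), 1)
    res = population_outcomes(sp)
    assert 0.0 <= res.surviving_fraction <= 1.0
    assert 0.0 <= res.tcp <= 1.0
    assert np.all(dose.total > 0)
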