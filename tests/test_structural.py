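"""Structural model: allometry, units, ODE behavior, reference vs compiled path."""

import numpy as np
import pytest
from scipy.linalg import expm

from cortdbs import _fastsim as fs
from cortdbs.binding import BindingParams, BloodGeometry, species_fractions, typical_geometry
from cortdbs.params import (
    AgeGroup,
    StructuralParams,
    allometric_scale,
    dose_to_nmol,
)
from cortdbs.structural import DoseEvent, ode_rhs, simulate_profile


def _pvec(p, b, g):
    return np.array([p.cl, g.v_c, p.q, p.v_p, p.km, p.vmax,
                     b.kd, b.bmax, b.ns_alb, b.kr, g.v_delta, p.f])


def test_allometric_identity_at_reference_weight():
    p = StructuralParams()
    assert allometric_scale(p, 70.0) == p


def test_allometric_values_and_composition():
    p = StructuralParams()
    s = allometric_scale(p, 13.5)
    assert s.cl == pytest.approx(400.0 * (13.5 / 70.0) ** 0.75, rel=1e-12)
    assert s.v_c == pytest.approx(10.6 * 13.5 / 70.0, rel=1e-12)
    assert s.km == p.km and s.vmax == p.vmax and s.f == p.f
    # power-law composition: scaling to w directly == scaling in two hops
    two_hop = allometric_scale(allometric_scale(p, 35.0), 13.5 * 70.0 / 35.0)
    direct = allometric_scale(p, 13.5)
    assert two_hop.cl == pytest.approx(direct.cl, rel=1e-12)


def test_nonpositive_weight_rejected():
    with pytest.raises(ValueError):
        allometric_scale(StructuralParams(), 0.0)


@pytest.mark.parametrize("mg,nmol", [(0.0, 0.0), (7.0, 7e6 / 362.46), (0.5, 5e5 / 362.46)])
def test_dose_conversion(mg, nmol):
    assert dose_to_nmol(mg) == pytest.approx(nmol, rel=1e-12)


def test_negative_dose_rejected():
    with pytest.raises(ValueError):
        dose_to_nmol(-1.0)


def test_rhs_empty_system_is_static(binding, child_geom):
    p = allometric_scale(StructuralParams(), child_geom.weight)
    assert ode_rhs((0.0, 0.0, 0.0), 0.0, p, binding, child_geom) == (0.0, 0.0, 0.0)


def test_rhs_half_saturation_absorption_rate(binding, child_geom):
    p = allometric_scale(StructuralParams(), child_geom.weight)
    d = ode_rhs((p.km, 0.0, 0.0), 0.0, p, binding, child_geom)
    assert -d[0] == pytest.approx(p.vmax / 2.0, rel=1e-12)
    assert -d[0] == pytest.approx(21388.0 / 2.0, rel=1e-12)


def test_zero_dose_gives_flat_baseline_profile(binding, child_geom):
    from dataclasses import replace
    p = replace(allometric_scale(StructuralParams(), child_geom.weight),
                base_pla=9.41, base_dbs=4.22)
    prof = simulate_profile([], p, binding, child_geom, np.linspace(0, 6, 25))
    np.testing.assert_allclose(prof.c_pla, 9.41)
    np.testing.assert_allclose(prof.c_dbs, 4.22)


def test_mass_balance_along_trajectory(binding, child_geom):
    p = allometric_scale(StructuralParams(), child_geom.weight)
    dose = DoseEvent(0.0, 7.0)
    prof = simulate_profile([dose], p, binding, child_geom, np.linspace(0, 8, 97))
    total = prof.a_depot + prof.a_central + prof.a_per + prof.a_elim
    np.testing.assert_allclose(total[1:], p.f * dose.amount_nmol, rtol=1e-6)
    for arr in (prof.a_depot, prof.a_central, prof.a_per, prof.c_pla, prof.c_dbs):
        assert np.all(arr >= 0)


def test_mass_balance_with_two_doses(binding, neonate_geom):
    p = allometric_scale(StructuralParams(), neonate_geom.weight)
    doses = [DoseEvent(0.0, 2.0), DoseEvent(3.0, 2.0)]
    prof = simulate_profile(doses, p, binding, neonate_geom, np.linspace(0, 8, 81))
    total = prof.a_depot + prof.a_central + prof.a_per + prof.a_elim
    # outputs at a dose instant report the pre-dose state
    expected = np.where(prof.times <= 3.0, 1, 2) * p.f * doses[0].amount_nmol
    np.testing.assert_allclose(total[1:], expected[1:], rtol=1e-6)


def test_first_order_limit_matches_linear_two_compartment_oracle(child_geom):
    """Km -> inf with Vmax/Km = ka fixed, Bmax = 0: the system is linear and
    its trajectory must match the matrix-exponential solution to 0.1%."""
    ka = 2.0
    km = 1e9
    p = StructuralParams(km=km, vmax=ka * km)
    p = allometric_scale(p, child_geom.weight)
    b = BindingParams(bmax=0.0, ns_alb=4.15, kr=0.92)
    dose = DoseEvent(0.0, 5.0)
    times = np.linspace(0, 6, 13)
    prof = simulate_profile([dose], p, b, child_geom, times)

    L = child_geom.v_c * b.linear_coupling  # Cu = A_central / L
    A = np.array([
        [-ka, 0.0, 0.0],
        [ka, -(p.cl + p.q) / L, p.q / p.v_p],
        [0.0, p.q / L, -p.q / p.v_p],
    ])
    y0 = np.array([dose.amount_nmol, 0.0, 0.0])
    for t, a_c in zip(times[1:], prof.a_central[1:]):
        oracle = (expm(A * t) @ y0)[1]
        assert a_c == pytest.approx(oracle, rel=1e-3)


def test_superposition_in_fully_linear_limit(child_geom):
    km = 1e9
    p = allometric_scale(StructuralParams(km=km, vmax=0.5 * km), child_geom.weight)
    b = BindingParams(bmax=0.0, ns_alb=4.15, kr=0.92)
    times = np.linspace(0, 6, 25)
    lo = simulate_profile([DoseEvent(0.0, 2.0)], p, b, child_geom, times)
    hi = simulate_profile([DoseEvent(0.0, 4.0)], p, b, child_geom, times)
    np.testing.assert_allclose(hi.c_dbs[1:], 2.0 * lo.c_dbs[1:], rtol=1e-3)


def test_exposure_monotone_in_dose(binding, child_geom):
    p = allometric_scale(StructuralParams(), child_geom.weight)
    times = np.linspace(0, 6, 61)
    cmax, auc = [], []
    for mg in (1.0, 2.0, 4.0, 7.0):
        prof = simulate_profile([DoseEvent(0.0, mg)], p, binding, child_geom, times)
        cmax.append(prof.cmax_dbs)
        auc.append(np.trapezoid(prof.c_dbs, times))
    assert np.all(np.diff(cmax) > 0) and np.all(np.diff(auc) > 0)


def test_trajectory_obeys_binding_ratio_identity(binding, neonate_geom):
    p = allometric_scale(StructuralParams(), neonate_geom.weight)
    prof = simulate_profile([DoseEvent(0.0, 4.0)], p, binding, neonate_geom,
                            np.linspace(0.1, 6, 30))
    *_, f_rbc = species_fractions(prof.c_dbs, binding, neonate_geom)
    expected = (1 + neonate_geom.v_delta / neonate_geom.v_c) * (1 - f_rbc)
    np.testing.assert_allclose(prof.c_pla / prof.c_dbs, expected, rtol=1e-6)


@pytest.mark.parametrize("group,mg,cmax_expected", [
    (AgeGroup.CHILDREN_INFANTS, 7.0, 180.0),
    (AgeGroup.NEONATE, 7.0, 820.0),
    (AgeGroup.NEONATE, 4.0, 767.5),
    (AgeGroup.CHILDREN_INFANTS, 4.0, 141.0),
])
def test_typical_whole_blood_cmax(binding, group, mg, cmax_expected):
    g = typical_geometry(group)
    p = allometric_scale(StructuralParams(), g.weight)
    prof = simulate_profile([DoseEvent(0.0, mg)], p, binding, g,
                            np.linspace(0, 6, 601))
    assert prof.cmax_dbs == pytest.approx(cmax_expected, rel=0.20)


def test_compiled_kernel_matches_reference_solver(binding, child_geom):
    p = allometric_scale(StructuralParams(), child_geom.weight)
    times = np.linspace(0, 12, 25)
    prof = simulate_profile([DoseEvent(0.0, 7.0)], p, binding, child_geom, times,
                            rtol=1e-10, atol=1e-12)
    c_pla, c_dbs = fs.simulate_observations(
        times, dose_to_nmol(7.0), _pvec(p, binding, child_geom),
        rtol=1e-10, atol=1e-12,
    )
    np.testing.assert_allclose(c_pla[1:], prof.c_pla[1:], rtol=1e-5)
    np.testing.assert_allclose(c_dbs[1:], prof.c_dbs[1:], rtol=1e-5)


def test_compiled_kernel_flags_pathological_parameters():
    p = np.array([1e300, 1.0, 1.0, 1.0, 1.0, 1e300,
                  9.71, 0.0, 0.0, 0.0, 0.0, 1.0])
    c_pla, c_dbs = fs.simulate_observations(np.array([0.0, 1.0]), 1e4, p)
    assert not np.all(np.isfinite(c_pla))
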