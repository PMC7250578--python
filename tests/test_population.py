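"""Linear population models: coefficient matrices, integration, fractions,
and the derived extra-centrosome observables."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from centroevo import (
    PopulationParams,
    PopulationState,
    build_matrix,
    extra_centrosome_fraction,
    fractions,
    initial_state,
    integrate,
    sc_share_of_extra,
)
from centroevo.population import fraction_ode_rhs


def test_matrix_entries_dld1(dld1):
    m = build_matrix(dld1, "II")
    assert m.labels == ("C2", "C4", "SC", "C6")
    # C2 self-term: b_C2(2q-1) - d_C2 = 1.2 * 0.95
    assert m.matrix[0, 0] == pytest.approx(1.14, abs=1e-12)
    # flux C2 -> SC: b_C2(1-q)v
    assert m.matrix[2, 0] == pytest.approx(1.2 * 0.025 * 0.22, rel=1e-12)
    # off-diagonals non-negative
    off = m.matrix - np.diag(np.diag(m.matrix))
    assert np.all(off >= 0)


def test_model2_with_v0_restricts_to_model1(dld1):
    p0 = dld1.replace(v=0.0)
    m1 = build_matrix(p0, "I").matrix
    m2 = build_matrix(p0, "II").matrix
    idx = [0, 1, 3]  # drop the SC row/column
    assert np.allclose(m2[np.ix_(idx, idx)], m1, atol=1e-15)
    # and trajectories agree when SC starts empty
    s0 = initial_state(0.10, 1.0, p0, "II", sc_seeding="none")
    t = np.linspace(0.1, 12, 40)
    x2 = integrate(build_matrix(p0, "II"), s0, t).states
    x1 = integrate(build_matrix(p0, "I"), PopulationState(0.0, 0.10, 0.90), t).states
    assert np.allclose(x2[:, [0, 1, 3]], x1, rtol=1e-10, atol=1e-12)
    assert np.allclose(x2[:, 2], 0.0, atol=1e-12)


def test_no_failure_no_flux_out_of_c2():
    p = PopulationParams(b_C2=1.0, b_C4=1.0, q=1.0, p_bipolar=1.0, r=1.0,
                         fs=1.0, d_C2=0.0, d_C4=0.0, d_C6=0.0)
    m = build_matrix(p, "I")
    assert m.matrix[1, 0] == 0.0  # (C4, C2) entry vanishes when q = 1


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        PopulationParams(b_C2=-1, b_C4=1, q=0.9, p_bipolar=0.3, r=0.5, fs=0.4,
                         d_C2=0, d_C4=0, d_C6=0)
    with pytest.raises(ValueError):
        PopulationParams(b_C2=1, b_C4=1, q=1.2, p_bipolar=0.3, r=0.5, fs=0.4,
                         d_C2=0, d_C4=0, d_C6=0)


@pytest.mark.parametrize(
    "alpha,v,expected",
    [
        (1.0, 0.22, (1.0, 0.0, 0.0, 0.0)),
        (0.10, 0.22, (0.10, 0.702, 0.198, 0.0)),
        (0.127, 0.32, (0.127, 0.59364, 0.27936, 0.0)),
    ],
)
def test_initial_state_seeding(alpha, v, expected, dld1):
    s = initial_state(alpha, 1.0, dld1.replace(v=v), "II")
    assert (s.C2, s.C4, s.SC, s.C6) == pytest.approx(expected, abs=1e-12)


def test_initial_state_model1_puts_all_extra_in_c4(dld1):
    s = initial_state(0.10, 1.0, dld1, "I")
    assert s.SC == 0.0 and s.C4 == pytest.approx(0.90)


def test_single_type_exponential_growth():
    """Closed-form limit: no deaths, all viable probabilities 1 → pure exponential."""
    p = PopulationParams(b_C2=0.7, b_C4=1.0, q=1.0, p_bipolar=1.0, r=1.0,
                         fs=1.0, d_C2=0.0, d_C4=0.0, d_C6=0.0)
    m = build_matrix(p, "I")
    s0 = PopulationState(0.0, 1.0, 0.0)
    traj = integrate(m, s0, [1.0, 2.0])
    assert traj.states[0, 0] == pytest.approx(np.exp(0.7), rel=1e-10)
    assert traj.states[1, 0] == pytest.approx(np.exp(1.4), rel=1e-10)


def test_zero_matrix_constant_trajectory():
    p = PopulationParams(b_C2=0, b_C4=0, q=1, p_bipolar=1, r=1, fs=1,
                         d_C2=0, d_C4=0, d_C6=0)
    m = build_matrix(p, "II")
    s0 = initial_state(0.3, 10.0, p, "II", sc_seeding="none")
    traj = integrate(m, s0, [5.0, 10.0])
    assert np.allclose(traj.states, [[3.0, 7.0, 0.0, 0.0]] * 2)


def test_expm_and_adaptive_integrator_agree(dld1_model2):
    matrix, s0 = dld1_model2
    t = np.linspace(0.5, 12, 24)
    a = integrate(matrix, s0, t, method="expm").states
    b = integrate(matrix, s0, t, method="ivp").states
    assert np.allclose(a, b, rtol=1e-8, atol=1e-12)


def test_times_validation(dld1_model2):
    matrix, s0 = dld1_model2
    with pytest.raises(ValueError):
        integrate(matrix, s0, [2.0, 1.0])
    with pytest.raises(ValueError):
        integrate(matrix, s0, [])


def test_fractions_sum_to_one_and_stay_nonnegative(rpe1_model2):
    matrix, s0 = rpe1_model2
    traj = integrate(matrix, s0, np.linspace(0.25, 30, 120))
    assert np.all(traj.states >= -1e-12)
    fr = fractions(traj)
    assert np.allclose(fr.fractions.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(fr.totals, traj.states.sum(axis=1))


def test_fraction_ode_oracle(dld1_model2):
    """Direct normalization of X(t) matches integrating the nonlinear fraction ODE."""
    matrix, s0 = dld1_model2
    t = np.linspace(0.5, 12, 24)
    fr = fractions(integrate(matrix, s0, t))
    f0 = s0.as_array() / s0.total
    sol = solve_ivp(lambda _t, f: fraction_ode_rhs(matrix.matrix, f), (0, 12), f0,
                    t_eval=t, rtol=1e-10, atol=1e-12)
    assert np.allclose(fr.fractions, sol.y.T, atol=1e-6)


def test_extra_fraction_and_sc_share():
    only_c2 = PopulationState(0.0, 1.0, 0.0)
    assert extra_centrosome_fraction(only_c2) == 0.0
    s = PopulationState(0.0, 0.10, 0.702, 0.198, 0.0)
    assert extra_centrosome_fraction(s) == pytest.approx(0.90)
    assert sc_share_of_extra(s) == pytest.approx(0.22)
    sc_only = PopulationState(0.0, 0.5, 0.0, 0.5, 0.0)
    assert sc_share_of_extra(sc_only) == 1.0
    # C6 convention is switchable
    s6 = PopulationState(0.0, 0.5, 0.25, 0.0, 0.25)
    assert extra_centrosome_fraction(s6, include_C6=True) == pytest.approx(0.5)
    assert extra_centrosome_fraction(s6, include_C6=False) == pytest.approx(0.25)
    with pytest.raises(ZeroDivisionError):
        extra_centrosome_fraction(PopulationState(0.0, 0.0, 0.0))
    with pytest.raises(ZeroDivisionError):
        sc_share_of_extra(only_c2)


def test_day12_extra_fraction_declines_from_day0(dld1_model2):
    matrix, s0 = dld1_model2
    traj = integrate(matrix, s0, [12.0])
    assert extra_centrosome_fraction(traj.final_state) < 0.90
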