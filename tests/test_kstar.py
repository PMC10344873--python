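import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bindscan.energetics import EnergyMatrix
from bindscan.kstar import (
    LN10,
    R_KCAL,
    DeltaKStar,
    KStarScore,
    delta_kstar,
    kstar_score,
    partition_function_bounded,
    partition_function_exhaustive,
)
from conftest import random_energy_matrix

RT = R_KCAL * 298.15


def single_conf_matrix(energy):
    return EnergyMatrix(energy, {(0, "X", 0): 0.0}, {}, [[(0, "X", 0)]])


def test_single_conformation_zero_energy_gives_unit_mass():
    pf = partition_function_exhaustive(single_conf_matrix(0.0))
    assert pf.log10_lower == pytest.approx(0.0, abs=1e-12)  # Z = 1


def test_single_conformation_closed_form():
    e = 2.718
    pf = partition_function_exhaustive(single_conf_matrix(e))
    assert pf.log10_lower == pytest.approx((-e / RT) / LN10, abs=1e-9)


def test_two_by_two_space_matches_hand_summed_boltzmann():
    # 2 positions x 2 rotamers nominally; here 2x1 and 1x2 kept tiny enough
    # to hand-sum the four Boltzmann terms
    k00, k01 = (0, "X", 0), (0, "X", 1)
    k10, k11 = (1, "X", 0), (1, "X", 1)
    singles = {k00: 0.5, k01: 1.0, k10: -0.5, k11: 0.25}
    pairs = {
        (k00, k10): 0.1, (k00, k11): -0.2,
        (k01, k10): 0.3, (k01, k11): 0.0,
    }
    m = EnergyMatrix(1.5, singles, pairs, [[k00, k01], [k10, k11]])
    energies = [
        1.5 + 0.5 - 0.5 + 0.1,
        1.5 + 0.5 + 0.25 - 0.2,
        1.5 + 1.0 - 0.5 + 0.3,
        1.5 + 1.0 + 0.25 + 0.0,
    ]
    z = sum(math.exp(-e / RT) for e in energies)
    pf = partition_function_exhaustive(m)
    assert pf.log10_lower == pytest.approx(math.log10(z), abs=1e-9)
    assert pf.n_enumerated == 4


def test_exhaustive_cap_advises_bounded():
    m = random_energy_matrix(np.random.default_rng(0), n_pos=4, n_rot=4)
    with pytest.raises(ValueError, match="bounded"):
        partition_function_exhaustive(m, cap=10)


def test_bounded_single_conformation_has_zero_gap():
    pf = partition_function_bounded(single_conf_matrix(1.0), epsilon=0.03)
    assert pf.relative_gap == pytest.approx(0.0, abs=1e-12)
    assert pf.log10_lower == pf.log10_upper


@pytest.mark.parametrize("epsilon", [0.03, 0.5, 0.99])
def test_bounded_brackets_exhaustive_on_random_spaces(rng, epsilon):
    for _ in range(25):
        m = random_energy_matrix(rng, n_pos=3, n_rot=3)
        ex = partition_function_exhaustive(m)
        pf = partition_function_bounded(m, epsilon=epsilon)
        assert pf.log10_lower - 1e-9 <= ex.log10_lower <= pf.log10_upper + 1e-9
        assert pf.relative_gap <= epsilon + 1e-12


def test_bounded_early_termination_saves_enumeration(rng):
    # with a generous epsilon the estimator should not enumerate everything
    m = random_energy_matrix(rng, n_pos=4, n_rot=4, sd=3.0)
    pf = partition_function_bounded(m, epsilon=0.5)
    assert pf.n_enumerated < m.n_conformations()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_bracketing_property_random_seeds(seed):
    """Exhaustive Z always lies inside the bounded bracket."""
    m = random_energy_matrix(np.random.default_rng(seed), n_pos=3, n_rot=4)
    ex = partition_function_exhaustive(m)
    pf = partition_function_bounded(m, epsilon=0.03)
    assert pf.log10_lower - 1e-9 <= ex.log10_lower <= pf.log10_upper + 1e-9


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(min_value=-100.0, max_value=1000.0))
def test_log_space_accumulation_no_overflow(energy):
    pf = partition_function_bounded(single_conf_matrix(energy), epsilon=0.03)
    assert np.isfinite(pf.log10_lower)


def test_epsilon_validation():
    with pytest.raises(ValueError):
        partition_function_bounded(single_conf_matrix(0.0), epsilon=0.0)
    with pytest.raises(ValueError):
        partition_function_bounded(single_conf_matrix(0.0), epsilon=1.0)


def pf_const(log10_z):
    from bindscan.kstar import PartitionFunctionResult

    return PartitionFunctionResult(log10_z, log10_z, 0.0, 1, 298.15)


def test_score_arithmetic():
    assert kstar_score(pf_const(0), pf_const(0), pf_const(0)).score == pytest.approx(0.0)
    s = kstar_score(pf_const(-5), pf_const(2), pf_const(3))
    assert s.score == pytest.approx(-10.0)


def test_complete_disruption_when_complex_mass_vanishes():
    s = kstar_score(pf_const(-400), pf_const(0), pf_const(0))
    assert s.status == "COMPLETE_DISRUPTION" and s.score is None


def test_zero_mass_unbound_partner_is_an_error():
    with pytest.raises(ValueError, match="partner"):
        kstar_score(pf_const(0), pf_const(-400), pf_const(0))


def test_delta_kstar_values_and_sentinel():
    wt = kstar_score(pf_const(1.0), pf_const(2.0), pf_const(1.54))
    mut = kstar_score(pf_const(-2.0), pf_const(2.0), pf_const(5.0))
    d = delta_kstar(mut, wt)
    assert d.value == pytest.approx(mut.score - wt.score)
    assert delta_kstar(wt, wt).value == pytest.approx(0.0)  # wildtype self-Δ
    disrupted = kstar_score(pf_const(-400), pf_const(0), pf_const(0))
    d = delta_kstar(disrupted, wt)
    assert d.is_complete_disruption and d.display == "X"
    with pytest.raises(ValueError):
        delta_kstar(mut, disrupted)


def test_monotonicity_raising_complex_pair_energies_lowers_kstar(rng):
    """Adding +δ to every complex pair energy strictly decreases K*."""
    m_complex = random_energy_matrix(rng, n_pos=3, n_rot=3)
    m_a = random_energy_matrix(rng, n_pos=2, n_rot=3)
    m_b = random_energy_matrix(rng, n_pos=1, n_rot=3)
    pf_a = partition_function_bounded(m_a, epsilon=0.03)
    pf_b = partition_function_bounded(m_b, epsilon=0.03)

    def score(mc):
        return kstar_score(
            partition_function_bounded(mc, epsilon=0.03), pf_a, pf_b
        ).score

    base = score(m_complex)
    shifted = EnergyMatrix(
        m_complex.template_energy,
        dict(m_complex.singles),
        {k: v + 0.7 for k, v in m_complex.pairs.items()},
        m_complex.position_keys,
    )
    assert score(shifted) < base
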