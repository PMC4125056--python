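"""Fluxes, the right-hand side and its conservation structure."""

import numpy as np
import pytest

from micellekin import (
    ModelParameters,
    StateVector,
    build_rate_table,
    fragmentation_kernel,
    micelle_fluxes,
    polymer_fluxes,
    rhs,
    total_mass,
)
from micellekin.baseline import rhs_baseline
from micellekin.model import NumericalStateError, boundary_mass_fraction, rhs_flat
from micellekin.parameters import BaselineParameters


def small_params(**kw):
    defaults = dict(a_mic=2.0, q_C=1.0, q_S=3.0, tau=4.0, d_off=5.0,
                    n_nucleus=4, beta=0.1, I_max=20, N_max=20)
    defaults.update(kw)
    return ModelParameters(**defaults)


def random_state(rng, I_max=20, N_max=20):
    s = StateVector.zeros(I_max, N_max)
    s.c = float(rng.uniform(0, 1))
    s.v = float(rng.uniform(0, 1))
    s.m = rng.uniform(0, 0.1, I_max - 1)
    s.u = rng.uniform(0, 0.1, N_max - 1)
    return s


class TestTotalMass:
    def test_monomer_only(self):
        s = StateVector.zeros(10, 10)
        s.c = 1.0
        assert total_mass(s) == 1.0

    def test_hand_summed_mixture(self):
        s = StateVector.zeros(10, 10)
        s.c = 0.2
        s.m[3 - 2] = 0.1       # 3-mer micelle: mass 0.3
        s.v = 0.1
        s.u[5 - 2] = 0.04      # 5-mer polymer: mass 0.2
        assert total_mass(s) == pytest.approx(0.8)


class TestMicelleFluxes:
    def test_empty_state_has_no_fluxes(self):
        p = small_params()
        s = StateVector.zeros(p.I_max, p.N_max)
        fx = micelle_fluxes(s, build_rate_table(p))
        assert np.all(fx.J_C == 0) and np.all(fx.J_S == 0)

    def test_pure_monomer_state_only_forms_dimers(self):
        p = small_params(a_mic=2.0)
        s = StateVector.zeros(p.I_max, p.N_max)
        s.c = 0.5
        fx = micelle_fluxes(s, build_rate_table(p))
        assert fx.J_C[0] == pytest.approx(2.0 * 0.5**2)
        assert np.all(fx.J_C[1:] == 0) and np.all(fx.J_S == 0)

    def test_detailed_balance_ladder_is_stationary(self):
        # ladder m_{i+1} = a*c*m_i / deplete_C_{i+1} with q_S = 0 nulls every flux
        p = small_params(q_S=0.0)
        rt = build_rate_table(p)
        s = StateVector.zeros(p.I_max, p.N_max)
        s.c = 0.3
        s.m[0] = p.a_mic * s.c**2 / rt.deplete_C[0]
        for k in range(1, s.m.size):
            s.m[k] = p.a_mic * s.c * s.m[k - 1] / rt.deplete_C[k]
        fx = micelle_fluxes(s, rt)
        assert np.allclose(fx.J_C, 0.0, atol=1e-14)
        # PrP* fluxes vanish too: v = 0 and deplete_S = 0
        assert np.allclose(fx.J_S, 0.0, atol=1e-14)
        d = rhs(s, rt)
        assert np.allclose(d.m, 0.0, atol=1e-13)


class TestPolymerFluxes:
    def test_no_fragmentation_without_beta(self):
        p = small_params(beta=0.0)
        rng = np.random.default_rng(0)
        s = random_state(rng)
        fx = polymer_fluxes(s, build_rate_table(p))
        assert np.all(fx.loss == 0) and np.all(fx.gain == 0)
        assert fx.monomer_return == 0.0

    def test_single_tetramer_enumerated_by_hand(self):
        # a 4-mer splits at rate 0.4 into (1,3), (2,2) or (3,1), each 1/3
        p = small_params(beta=0.1)
        s = StateVector.zeros(p.I_max, p.N_max)
        s.u[4 - 2] = 1.0
        fx = polymer_fluxes(s, build_rate_table(p))
        sizes = np.arange(2, p.N_max + 1)
        assert fx.loss[sizes == 4][0] == pytest.approx(0.4)
        assert fx.gain[sizes == 2][0] == pytest.approx(2 * 0.4 / 3)
        assert fx.gain[sizes == 3][0] == pytest.approx(2 * 0.4 / 3)
        assert fx.monomer_return == pytest.approx(2 * 0.4 / 3)
        created = float(sizes @ fx.gain) + fx.monomer_return
        assert created == pytest.approx(4 * 0.4)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_fragmentation_is_mass_neutral(self, seed):
        p = small_params()
        s = random_state(np.random.default_rng(seed))
        fx = polymer_fluxes(s, build_rate_table(p))
        sizes = np.arange(2, p.N_max + 1)
        net = float(sizes @ (fx.gain - fx.loss)) + fx.monomer_return
        assert net == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_bookkeeping_matches_cut_enumeration(self, seed):
        """Suffix-sum gains equal a brute-force loop over all (j, cut) events."""
        p = small_params()
        rt = build_rate_table(p)
        s = random_state(np.random.default_rng(seed))
        fx = polymer_fluxes(s, rt)

        gain = np.zeros(p.N_max + 1)  # indexed by fragment size, 1..N_max
        for idx, j in enumerate(range(2, p.N_max + 1)):
            rate = rt.frag[idx] * s.u[idx]
            for k in range(1, j):
                w = rate * fragmentation_kernel(k, j)
                gain[k] += w
                gain[j - k] += w
        assert np.allclose(fx.gain, gain[2:], rtol=1e-12, atol=1e-15)
        assert fx.monomer_return == pytest.approx(gain[1], rel=1e-12)


class TestRhs:
    def test_zero_state_zero_derivative(self):
        p = small_params()
        s = StateVector.zeros(p.I_max, p.N_max)
        d = rhs(s, build_rate_table(p))
        assert d.c == 0 and d.v == 0
        assert np.all(d.m == 0) and np.all(d.u == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_vector_field_conserves_mass(self, seed):
        p = small_params()
        s = random_state(np.random.default_rng(seed))
        d = rhs(s, build_rate_table(p))
        rate = total_mass(d)  # total_mass is linear, so this is d(mass)/dt
        assert abs(rate) < 1e-12 * total_mass(s)

    def test_rejects_non_finite_state(self):
        p = small_params()
        s = StateVector.zeros(p.I_max, p.N_max)
        s.c = np.nan
        with pytest.raises(NumericalStateError):
            rhs(s, build_rate_table(p))

    def test_flat_and_structured_rhs_agree(self):
        p = small_params()
        rt = build_rate_table(p)
        s = random_state(np.random.default_rng(11))
        d_struct = rhs(s, rt)
        d_flat = StateVector.from_flat(rhs_flat(0.0, s.to_flat(), rt), p.I_max)
        assert d_struct.c == pytest.approx(d_flat.c)
        assert d_struct.v == pytest.approx(d_flat.v)
        assert np.allclose(d_struct.m, d_flat.m)
        assert np.allclose(d_struct.u, d_flat.u)

    def test_reduces_to_baseline_when_micelles_off(self):
        """With micelle rates zeroed, the PrP* subsystem follows the
        nucleation-dependent comparator exactly (v playing the monomer)."""
        p = small_params(a_mic=0.0, q_C=0.0, q_S=0.0)
        rt = build_rate_table(p)
        rng = np.random.default_rng(5)
        s = StateVector.zeros(p.I_max, p.N_max)
        s.v = 0.4
        s.u = rng.uniform(0, 0.05, p.N_max - 1)

        d = rhs(s, rt)
        bp = BaselineParameters(tau=p.tau, d_off=p.d_off, n_nucleus=p.n_nucleus,
                                beta=p.beta, N_max=p.N_max)
        dc, du = rhs_baseline(s.v, s.u, bp)
        assert d.v == pytest.approx(dc)
        assert np.allclose(d.u, du)
        assert d.c == 0 and np.all(d.m == 0)


class TestBoundaryDiagnostics:
    def test_boundary_fraction_flags_heavy_top_sizes(self):
        s = StateVector.zeros(20, 20)
        s.u[-1] = 1.0  # all mass at the polymer truncation boundary
        mic, pol = boundary_mass_fraction(s)
        assert mic == 0.0 and pol == pytest.approx(1.0)
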