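"""Fixed points, mode-reduced spectra, pitchfork and Hopf location."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import bisect

from repressilator import model
from repressilator.equilibria import (
    ParityError,
    dimerized_fixed_points,
    find_hopf_points,
    find_pitchfork,
    mode_spectrum,
    symmetric_fixed_point,
)
from repressilator.model import jacobian


def _bisection_oracle(c):
    """Independent root of p (1 + p^2) = c by plain bisection."""
    return bisect(lambda p: p * (1 + p * p) - c, 0.0, max(c, 1.0), xtol=1e-12)


class TestSymmetricFixedPoint:
    @pytest.mark.parametrize("c", [2.0, 3.0, 4.68, 72.22])
    def test_matches_bisection_oracle(self, c):
        p = model.preset("table1", n=6).with_c(c)
        fp = symmetric_fixed_point(p)
        assert fp.p_m == pytest.approx(_bisection_oracle(c), abs=1e-10)
        assert fp.p_m * (1 + fp.p_m**2) == pytest.approx(c, abs=1e-10)
        assert fp.m_m == pytest.approx(0.06 / 0.16 * fp.p_m)

    def test_known_values(self):
        p = model.preset("table1", n=6)
        assert symmetric_fixed_point(p.with_c(2.0)).p_m == pytest.approx(1.0, abs=1e-12)
        assert symmetric_fixed_point(p.with_c(4.68)).p_m == pytest.approx(1.47446, abs=1e-4)
        assert symmetric_fixed_point(p.with_c(3.0)).p_m == pytest.approx(1.2134, abs=1e-4)


class TestDimerizedFixedPoints:
    def test_closed_form_at_c_2_5(self):
        p = model.preset("table1", n=6).with_c(2.5)
        fp = dimerized_fixed_points(p)[0]
        assert (fp.p_u, fp.p_d) == (pytest.approx(2.0), pytest.approx(0.5))

    def test_degenerate_at_pitchfork(self):
        fp = dimerized_fixed_points(model.preset("table1", n=4).with_c(2.0))[0]
        assert fp.p_u == fp.p_d == pytest.approx(1.0)

    def test_large_c_limits(self):
        c = 100.0
        fp = dimerized_fixed_points(model.preset("table1", n=6).with_c(c))[0]
        assert fp.p_u == pytest.approx(c - 1.0 / c, rel=1e-3)
        assert fp.p_d == pytest.approx(1.0 / c, rel=1e-3)

    def test_below_pitchfork_empty_and_odd_ring_error(self):
        assert dimerized_fixed_points(model.preset("table1", n=6).with_c(1.5)) == []
        with pytest.raises(ParityError):
            dimerized_fixed_points(model.preset("table1", n=3))

    @given(st.floats(min_value=2.001, max_value=100.0))
    def test_product_and_sum_identities(self, c):
        fp = dimerized_fixed_points(model.preset("table1", n=6).with_c(c))[0]
        assert fp.p_u * fp.p_d == pytest.approx(1.0, abs=1e-10)
        assert fp.p_u + fp.p_d == pytest.approx(c, abs=1e-10)
        assert fp.p_u >= fp.p_d


def _match_spectra(a, b):
    """Max distance under optimal pairing of two eigenvalue multisets."""
    from scipy.optimize import linear_sum_assignment

    D = np.abs(a[:, None] - b[None, :])
    r, c = linear_sum_assignment(D)
    return D[r, c].max()


class TestModeSpectrum:
    @pytest.mark.parametrize("n, c", [(4, 1.0), (6, 5.0), (9, 3.3), (12, 20.0)])
    def test_union_equals_dense_jacobian_spectrum(self, n, c):
        p = model.preset("table1", n=n).with_c(c)
        y = symmetric_fixed_point(p).state(n)
        dense = np.linalg.eigvals(jacobian(y, p))
        modes = np.array([l for m in mode_spectrum(p) for l in m.lambdas])
        assert _match_spectra(dense, modes) < 1e-8

    def test_random_parameter_sets(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 11))
            p = model.RingParameters(
                n=n,
                c1=rng.uniform(0.05, 3.0),
                c2=rng.uniform(0.02, 0.5),
                c3=rng.uniform(0.02, 0.5),
                c4=rng.uniform(0.02, 0.5),
            )
            y = symmetric_fixed_point(p).state(n)
            dense = np.linalg.eigvals(jacobian(y, p))
            modes = np.array([l for m in mode_spectrum(p) for l in m.lambdas])
            assert _match_spectra(dense, modes) < 1e-8

    def test_pitchfork_mode_root_vanishes_at_c_2(self):
        p = model.preset("table1", n=6).with_c(2.0)
        lams = mode_spectrum(p)[3].lambdas  # k = n/2
        assert min(abs(l) for l in lams) < 1e-10

    def test_stable_below_pitchfork(self):
        p = model.preset("table1", n=8).with_c(0.5)
        assert all(l.real < 0 for m in mode_spectrum(p) for l in m.lambdas)


class TestBifurcations:
    @pytest.mark.parametrize("n", [2, 4, 6, 10, 18, 20])
    def test_pitchfork_at_two_for_even_rings(self, n):
        bp = find_pitchfork(model.preset("table1", n=n))
        assert bp.c_star == pytest.approx(2.0, abs=1e-9)
        assert bp.mode_k == n // 2

    def test_pitchfork_parity_error(self):
        with pytest.raises(ParityError):
            find_pitchfork(model.preset("table1", n=3))

    def test_n6_first_hopf(self):
        hbs = find_hopf_points(model.preset("table1", n=6))
        assert len(hbs) == 1
        assert hbs[0].period == pytest.approx(132.17, abs=0.05)

    def test_n12_second_hopf_doubles_n6_first(self):
        h6 = find_hopf_points(model.preset("table1", n=6))[0]
        h12 = find_hopf_points(model.preset("table1", n=12))[1]
        assert h12.c_star == pytest.approx(h6.c_star, abs=1e-4)
        assert h12.period == pytest.approx(h6.period, abs=1e-3)
        assert h12.mode_k == 2 * h6.mode_k

    def test_odd_ring_first_hopf_decreases_toward_two(self):
        cs = [
            find_hopf_points(model.preset("table1", n=n))[0].c_star
            for n in range(3, 24, 2)
        ]
        assert all(a > b for a, b in zip(cs, cs[1:]))
        assert cs[-1] > 2.0
        assert cs[-1] - 2.0 < 0.15


def test_bifurcation_table_schema(tmp_path):
    from repressilator.equilibria import bifurcation_table

    df = bifurcation_table(model.preset("table1", n=10))
    assert list(df.columns) == ["n", "type", "c", "mode_k", "omega", "period_min"]
    assert (df["type"] == "P").sum() == 1
    assert (df["type"] == "HB").sum() == 2
    path = tmp_path / "bif.csv"
    df.to_csv(path, index=False)
    assert path.read_text().splitlines()[0] == "n,type,c,mode_k,omega,period_min"
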