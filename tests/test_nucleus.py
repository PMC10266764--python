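"""Nested Pump-Leak model: analytic regime, scaling law, envelope mechanics."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import fsolve

from cellscale import nucleus as nu
from cellscale.constants import CONC_UM3_PER_COUNT as GAMMA
from cellscale.pumpleak import volume_infinite_pumping


class TestClosedForms:
    @pytest.mark.parametrize(
        "qeff, n0, expected",
        [(0.0, 150.0, 0.0), (300.0, 150.0, -math.log(2)), (30.0, 150.0, -math.log(1.1))],
    )
    def test_nuclear_potential(self, qeff, n0, expected):
        assert nu.nuclear_potential(qeff, n0) == pytest.approx(expected, abs=1e-12)

    def test_nuclear_potential_saturates_at_ln2(self, nested_params):
        # in the solved system the chromatin charge concentration cannot
        # exceed 2 n0 (the nucleus swells with its counterions), so the
        # envelope potential bottoms out at -ln 2
        p = replace(nested_params, Qeff=1e13, Af_tot=1e10)
        st = nu.solve_nested(p, mechanics=False)
        assert st.Un == pytest.approx(-math.log(2), abs=2e-3)
        assert st.Un > -math.log(2)

    def test_nc_limits(self):
        nc1, nc2 = nu.nc_limits(1e9, 3.3e9, 0.0)
        assert nc1 == nc2
        nc1, nc2 = nu.nc_limits(1e9, 2e9, 6e9)
        assert nc2 == pytest.approx(4 * nc1, rel=1e-12)

    @pytest.mark.parametrize("NC, frac", [(1.0, 0.5), (1.0 / 3.0, 0.25), (1e9, 1.0)])
    def test_metabolite_partition(self, NC, frac):
        assert nu.metabolite_partition(10.0, NC) == pytest.approx(10.0 * frac, rel=1e-6)

    def test_pressure_regime_volume(self):
        pn_count = 1e9
        v_osm = nu.nuclear_volume_pressure_regime(pn_count, 0.0, 10.0)
        assert v_osm == pytest.approx(pn_count * GAMMA / 10.0, rel=1e-12)
        # 1000 Pa is 0.401 mM at 300 K: volume shrinks by 1/(1 + 0.401)
        v = nu.nuclear_volume_pressure_regime(pn_count, 1000.0, 1.0, T=300.0)
        assert v == pytest.approx(v_osm * 10.0 / (1.0 + 0.40097), rel=1e-4)


class TestEnvelopeMechanics:
    def test_tension_free_within_fold_reserve(self):
        viso = 300.0
        vmax_area = viso * (1.04) ** 1.5
        gamma, dpn = nu.envelope_tension(vmax_area * 0.999, viso, 0.04, 50.0)
        assert gamma == 0.0 and dpn == 0.0

    def test_linear_elasticity_beyond_unfolding(self):
        viso, s, K = 300.0, 0.04, 50.0
        a0 = nu._sphere_area(viso) * (1 + s)
        v1, v2 = viso * 1.2, viso * 1.25
        g1, _ = nu.envelope_tension(v1, viso, s, K)
        g2, _ = nu.envelope_tension(v2, viso, s, K)
        dg_da = (g2 - g1) / (nu._sphere_area(v2) - nu._sphere_area(v1))
        assert dg_da == pytest.approx(K / a0, rel=1e-9)

    def test_max_swelling_stiff_limit_is_area_bound(self, nested_params):
        p = replace(nested_params, K=1e9, Vn_iso=300.0)
        assert nu.max_swelling(p) == pytest.approx((1 + p.s) ** 1.5, rel=1e-4)

    def test_max_swelling_soft_limit_diverges(self, nested_params):
        p1 = replace(nested_params, K=1e-3, Vn_iso=300.0)
        p2 = replace(nested_params, K=1e-5, Vn_iso=300.0)
        ratio = nu.max_swelling(p2) / nu.max_swelling(p1)
        assert ratio == pytest.approx(100 ** 0.75, rel=0.05)


def _oracle_solve(p: nu.NestedParams):
    """Independent route: raw concentration variables, generic solver."""

    def eqs(v):
        wn, wc, acf, ncp, un = v
        pn, pc = p.Pn * GAMMA / wn, p.Pc * GAMMA / wc
        qeff = p.Qeff * GAMMA / wn
        anf = acf * math.exp(p.za * un)
        ncm = p.alpha0 * p.n0**2 / ncp
        nnp, nnm = ncp * math.exp(-un), ncm * math.exp(un)
        return [
            ncp - ncm - p.zp * pc - p.za * acf,
            nnp - nnm - p.zp * pn - p.za * anf - qeff,
            ncp + ncm + pc + acf - 2 * p.n0,
            nnp + nnm + pn + anf - (ncp + ncm + pc + acf),
            acf * wc + anf * wn - p.Af_tot * GAMMA,
        ]

    w0 = ((p.zp + 1) * (p.Pn + p.Pc) + (p.za + 1) * p.Af_tot + p.Qeff) * GAMMA / (2 * p.n0)
    v0 = [w0 * 0.3, w0 * 0.7, p.Af_tot * GAMMA / w0, p.n0, -0.05]
    sol, info, ier, msg = fsolve(eqs, v0, full_output=True)
    assert ier == 1, msg
    return sol


class TestSolver:
    def test_symmetric_compartments_have_no_potential(self):
        p = nu.NestedParams(Pn=2e9, Pc=4e9, Af_tot=0.0, Qeff=0.0)
        st = nu.solve_nested(p, mechanics=False)
        assert st.Un == pytest.approx(0.0, abs=1e-12)
        assert st.NC == pytest.approx(0.5, rel=1e-10)
        assert st.pn == pytest.approx(st.pc, rel=1e-10)

    def test_analytic_monovalent_regime(self, nested_params):
        # zp = za = 1, alpha0 = 0: nc = n0, nn = n0 + qeff/2, Un from the
        # chromatin charge concentration
        st = nu.solve_nested(nested_params, mechanics=False)
        assert st.nc_plus == pytest.approx(nested_params.n0, rel=1e-9)
        assert st.nn_plus == pytest.approx(nested_params.n0 + st.qeff / 2, rel=1e-9)
        assert st.Un == pytest.approx(
            nu.nuclear_potential(st.qeff, nested_params.n0), abs=1e-9
        )
        assert np.max(np.abs(st.residuals())) < 1e-9

    def test_against_independent_solver(self, nested_params):
        st = nu.solve_nested(nested_params, mechanics=False)
        wn, wc, acf, ncp, un = _oracle_solve(nested_params)
        assert st.Vn == pytest.approx(wn, rel=1e-6)
        assert st.Vc == pytest.approx(wc, rel=1e-6)
        assert st.Un == pytest.approx(un, rel=1e-6)

    def test_total_volume_matches_single_compartment(self, nested_params):
        # tension-free: total cell volume obeys the one-compartment law with
        # all trapped species, metabolites and chromatin counterions pooled
        p = nested_params
        st = nu.solve_nested(p, mechanics=False)
        x_equiv = (p.zp + 1) * (p.Pn + p.Pc) + (p.za + 1) * p.Af_tot + p.Qeff
        v_total = volume_infinite_pumping(x_equiv, 0.0, p.n0, R=0.0)
        assert st.Vn + st.Vc == pytest.approx(v_total, rel=1e-9)

    def test_metabolite_conservation(self, nested_params):
        p = nested_params
        st = nu.solve_nested(p, mechanics=False)
        total = st.acf * (st.Vc - p.Rc) + st.anf * (st.Vn - p.Rn)
        assert total == pytest.approx(p.Af_tot * GAMMA, rel=1e-10)

    def test_nc_between_limits_and_metabolite_sweep(self, nested_params):
        p = nested_params
        nc1, nc2 = nu.nc_limits(p.Pn, p.Pc, p.Qeff)
        ncs = []
        for af in [0.0, 1e9, 1e10, 1e11, 1e12, 1e13]:
            st = nu.solve_nested(replace(p, Af_tot=af), mechanics=False)
            ncs.append(st.NC)
            assert nc1 - 1e-9 <= st.NC <= nc2 + 1e-9
        # monotone approach NC2 -> NC1 as the metabolite pool grows
        assert np.all(np.diff(ncs) < 0)
        assert ncs[0] == pytest.approx(nc2, rel=1e-6)
        assert ncs[-1] == pytest.approx(nc1, rel=1e-3)

    def test_envelope_potential_independent_of_external_concentration(self, nested_params):
        # fixed counts: volumes scale as 1/n0 so the chromatin charge
        # concentration relative to n0, and hence Un, is invariant
        uns = [
            nu.solve_nested(replace(nested_params, n0=n0), mechanics=False).Un
            for n0 in (50.0, 100.0, 150.0, 300.0)
        ]
        assert np.allclose(uns, uns[0], atol=1e-10)

    def test_linear_scaling_identity_per_state(self, nested_params):
        # per solved tension-free state the scaling law is exact
        p = replace(nested_params, Rn=20.0, Rc=80.0)
        st = nu.solve_nested(p, mechanics=False)
        slope, intercept = nu.linear_scaling(p, st)
        assert st.Vn == pytest.approx(slope * st.Vc + intercept, rel=1e-10)
        assert intercept == pytest.approx(p.Rn - slope * p.Rc, rel=1e-12)

    def test_linear_scaling_under_metabolite_sweep(self, nested_params):
        # diluted chromatin: the slope is metabolite independent, so a sweep
        # of the pool traces the predicted line
        p = replace(nested_params, Qeff=0.0, Rn=10.0, Rc=40.0)
        vns, vcs = [], []
        for af in np.linspace(0.5, 2.0, 7) * p.Af_tot:
            st = nu.solve_nested(replace(p, Af_tot=af), mechanics=False)
            vns.append(st.Vn)
            vcs.append(st.Vc)
        coeffs = np.polyfit(vcs, vns, 1)
        pred = np.polyval(coeffs, vcs)
        ss_res = np.sum((np.array(vns) - pred) ** 2)
        ss_tot = np.sum((np.array(vns) - np.mean(vns)) ** 2)
        assert 1 - ss_res / ss_tot > 1 - 1e-10
        st0 = nu.solve_nested(p, mechanics=False)
        slope, intercept = nu.linear_scaling(p, st0)
        assert coeffs[0] == pytest.approx(slope, rel=1e-8)
        assert coeffs[1] == pytest.approx(intercept, rel=1e-6)

    def test_linear_scaling_rejects_tensed_state(self, nested_params):
        p = nested_params
        st = nu.solve_nested(p, mechanics=False)
        tensed = replace(st, gamma_n=1.0)
        with pytest.raises(ValueError):
            nu.linear_scaling(p, tensed)

    def test_metabolite_partition_neutral_limit(self, nested_params):
        # za = 0: the nuclear metabolite count follows the NC ratio exactly
        p = replace(nested_params, za=0.0)
        st = nu.solve_nested(p, mechanics=False)
        anf_count = st.anf * (st.Vn - p.Rn) / GAMMA
        assert anf_count == pytest.approx(
            nu.metabolite_partition(p.Af_tot, st.NC), rel=1e-9
        )


@pytest.fixture(scope="module")
def sweep(nested_params):
    grid = nested_params.n0 * np.geomspace(1.0, 1e-8, 50)
    return nu.osmotic_shock_sweep(nested_params, grid)


@pytest.fixture(scope="module")
def yeast_traj():
    from cellscale import growth as g

    return g.simulate_growth(g.default_growth_params(), np.linspace(0.0, 1.4, 15))


class TestShock:
    def test_swelling_monotone_under_dilution(self, sweep):
        assert np.all(np.diff(sweep["Vn_norm"]) >= -1e-12)

    def test_plateau_matches_closed_form(self, nested_params, sweep):
        iso = nu.solve_nested(nested_params, mechanics=False)
        vmax = nu.max_swelling(replace(nested_params, Vn_iso=iso.Vn))
        assert sweep["Vn_norm"].iloc[-1] == pytest.approx(vmax, rel=1e-6)

    def test_constant_content_counterfactual_overshoots(self, sweep):
        # metabolites leave the nucleus during the shock, so freezing the
        # nuclear content overestimates swelling everywhere
        assert np.all(
            sweep["Vn_norm_counterfactual"] >= sweep["Vn_norm"] - 1e-12
        )
        assert sweep["Vn_norm_counterfactual"].iloc[-1] > 2 * sweep["Vn_norm"].iloc[-1]

    def test_nc_ratio_collapses_under_strong_shock(self, sweep):
        assert sweep["NC"].iloc[-1] < 0.01 * sweep["NC"].iloc[0]


class TestGrowthNC:
    def test_large_metabolite_pool_holds_nc(self, nested_params, yeast_traj):
        p = replace(nested_params, Qeff=5e6)
        df = nu.simulate_growth_nc(p, yeast_traj, fn=0.25)
        drift = abs(df["NC"].iloc[-1] / df["NC"].iloc[0] - 1)
        assert drift < 0.02  # volume doubles, NC moves by < 2%

    def test_without_metabolites_nc_decays(self, nested_params, yeast_traj):
        p = replace(nested_params, Qeff=5e6)
        traj = yeast_traj.copy()
        traj["Af"] = 0.0
        df = nu.simulate_growth_nc(p, traj, fn=0.25)
        assert np.all(np.diff(df["NC"]) < 0)

    def test_nc_drift_and_potential_rank_with_chromatin_charge(
        self, nested_params, yeast_traj
    ):
        drifts, potentials = [], []
        for qeff in (5e6, 5e7, 2e8):
            df = nu.simulate_growth_nc(
                replace(nested_params, Qeff=qeff), yeast_traj, fn=0.25
            )
            drifts.append(abs(df["NC"].iloc[-1] / df["NC"].iloc[0] - 1))
            potentials.append(abs(df["Un"]).max())
        assert np.all(np.diff(drifts) > 0)
        assert np.all(np.diff(potentials) > 0)
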