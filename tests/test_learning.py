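"""Learning rules and occupancy statistics, validated against independent oracles."""
import numpy as np
import pytest

from synmem.patterns import generate_prototypes
from synmem.learning import (
    PlasticityParams,
    SynapticMatrix,
    learn_mp,
    learn_sp,
    learn_willshaw,
    mp_occupancy,
    mp_occupancy_finite,
    present_pattern,
    sp_occupancy,
    stationary_init,
    willshaw_occupancy,
)


class TestPlasticityParams:
    def test_ratio_resolution_both_ways(self):
        f = 0.05
        p1 = PlasticityParams(q_plus=0.4, q_minus=0.02)
        qp, qm, g = p1.resolve(f)
        # depressing events / potentiating events per presentation
        assert g == pytest.approx(0.02 * (1 - f) / (0.4 * f))
        p2 = PlasticityParams(q_plus=0.4, g_ratio=g)
        assert p2.resolve(f)[1] == pytest.approx(0.02)

    def test_inconsistent_specification_raises(self):
        p = PlasticityParams(q_plus=0.4, q_minus=0.02, g_ratio=5.0)
        with pytest.raises(ValueError, match="inconsistent"):
            p.resolve(0.05)

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            PlasticityParams(q_plus=1.5, g_ratio=1.0)
        with pytest.raises(ValueError):
            PlasticityParams(q_plus=0.5)  # neither q_minus nor g_ratio


class TestWillshaw:
    def test_empty_pattern_set_gives_zero_matrix(self):
        ps = generate_prototypes(50, 0, f=0.2, seed=0)
        assert learn_willshaw(ps).J.sum() == 0

    def test_single_pattern_block(self):
        ps = generate_prototypes(60, 1, m_fixed=8, seed=2)
        J = learn_willshaw(ps).J
        sel = ps.selective_indices(0)
        expect = np.zeros((60, 60), dtype=np.uint8)
        expect[np.ix_(sel, sel)] = 1
        np.fill_diagonal(expect, 0)
        assert np.array_equal(J, expect)

    def test_potentiated_fraction_matches_bernoulli_oracle(self):
        """Conditional on the realised pattern sizes, each synapse pair is
        potentiated independently with probability 1 - prod(1 - p_mu)."""
        N, f, P = 2000, 0.05, 100
        ps = generate_prototypes(N, P, f=f, seed=9)
        frac = learn_willshaw(ps).potentiated_fraction
        Ms = ps.row_sums.astype(float)
        p_mu = Ms * (Ms - 1) / (N * (N - 1))
        expected_cond = 1 - np.prod(1 - p_mu)
        n_pairs = N * (N - 1)
        se = np.sqrt(expected_cond * (1 - expected_cond) / n_pairs)
        # pairs sharing a neuron are weakly correlated: allow an inflated band
        assert abs(frac - expected_cond) < 12 * se
        # unconditional closed form, up to quenched pattern-size fluctuations
        assert frac == pytest.approx(1 - (1 - f * f) ** P, abs=0.01)

    def test_occupancy_closed_form(self):
        assert willshaw_occupancy(0.3, 0).g_minus == 0.0
        occ = willshaw_occupancy(0.1, 100)
        assert occ.g_plus == 1.0
        assert occ.g_minus == pytest.approx(1 - (1 - 0.01) ** 100, abs=1e-12)
        assert occ.g_minus == pytest.approx(0.6339676587, abs=1e-9)


class TestSPRule:
    def test_no_transitions_when_rates_zero(self):
        ps = generate_prototypes(100, 10, f=0.1, seed=1)
        J0 = stationary_init(100, 0.4, np.random.default_rng(0))
        out = learn_sp(ps, PlasticityParams(q_plus=0.0, q_minus=0.0), seed=3, init=J0)
        assert np.array_equal(out.J, J0)

    def test_deterministic_ltp_on_single_pattern(self):
        ps = generate_prototypes(80, 1, m_fixed=10, seed=4)
        out = learn_sp(ps, PlasticityParams(q_plus=1.0, q_minus=0.0), seed=5, init="zero")
        sel = ps.selective_indices(0)
        expect = np.zeros((80, 80), dtype=np.uint8)
        expect[np.ix_(sel, sel)] = 1
        np.fill_diagonal(expect, 0)
        assert np.array_equal(out.J, expect)

    def test_markov_transition_frequencies(self):
        """Empirical per-synapse transition rates match the update rule."""
        rng = np.random.default_rng(6)
        N, f = 300, 0.1
        q_plus, q_minus = 0.3, 0.1
        J = stationary_init(N, 0.5, rng)
        pot_events = pot_ops = dep_events = dep_ops = 0
        untouched_changed = 0
        for _ in range(60):
            act = np.flatnonzero(rng.random(N) < f)
            pre = np.zeros(N, dtype=bool); pre[act] = True
            J_old = J.copy()
            present_pattern(J, act, q_plus, q_minus, rng)
            both = np.ix_(act, act)
            eligible_pot = (J_old[both] == 0)
            np_mask = ~pre
            dep_block = np.ix_(np.flatnonzero(np_mask), act)
            eligible_dep = (J_old[dep_block] == 1)
            pot_ops += eligible_pot.sum() - len(act)  # exclude diagonal cells
            pot_events += ((J[both] == 1) & eligible_pot).sum()
            dep_ops += eligible_dep.sum()
            dep_events += ((J[dep_block] == 0) & eligible_dep).sum()
            # synapses with silent presynaptic neuron never change
            silent_cols = np.flatnonzero(~pre)
            untouched_changed += (J[:, silent_cols] != J_old[:, silent_cols]).sum()
        assert untouched_changed == 0
        for events, ops, q in ((pot_events, pot_ops, q_plus), (dep_events, dep_ops, q_minus)):
            se = np.sqrt(q * (1 - q) / ops)
            assert abs(events / ops - q) < 4 * se, (events / ops, q, ops)

    def test_stationary_fraction_matches_markov_chain(self):
        """Long-stream potentiated fraction converges to the stationary value
        of the per-synapse two-state chain, computed independently."""
        N, f = 400, 0.08
        params = PlasticityParams(q_plus=0.5, g_ratio=1.0)
        qp, qm, _ = params.resolve(f)
        # independent two-state chain: up-rate f^2 qp, down-rate f(1-f) qm
        a, b = f * f * qp, f * (1 - f) * qm
        g_stat = a / (a + b)
        ps = generate_prototypes(N, 3000, f=f, seed=12)
        out = learn_sp(ps, params, seed=13, init="zero")
        frac = out.potentiated_fraction
        se = np.sqrt(g_stat * (1 - g_stat) / (N * (N - 1)))
        # synapses are weakly correlated; allow a generous multiple of the
        # independent-pair standard error
        assert abs(frac - g_stat) < 12 * se

    def test_occupancy_age_dependence(self):
        params = PlasticityParams(q_plus=0.05, g_ratio=0.7)
        f = 0.001
        occs = [sp_occupancy(K, params, f) for K in (1, 10, 100, 1000, 10000)]
        gps = [o.g_plus for o in occs]
        assert all(a >= b for a, b in zip(gps, gps[1:]))  # non-increasing
        assert all(o.g_plus >= o.g_inf for o in occs)
        assert sp_occupancy(1, PlasticityParams(q_plus=1.0, g_ratio=0.7), f).g_plus == 1.0
        # K -> infinity converges to g_inf (decay time is ~1/(f^2 q_plus (1+g)))
        assert sp_occupancy(10**9, params, f).g_plus == pytest.approx(occs[0].g_inf, rel=1e-6)

    def test_occupancy_against_simulation(self):
        """g_plus(K) from the closed form matches tracked synapses in learn_sp."""
        N, f, K = 400, 0.05, 30
        params = PlasticityParams(q_plus=0.5, g_ratio=1.0)
        hits = tot = 0
        for rep in range(200):
            stream = generate_prototypes(N, K, f=f, seed=1000 + rep)
            sm = learn_sp(stream, params, seed=2000 + rep, init="stationary")
            sel = stream.selective_indices(0)  # oldest pattern has age K
            if sel.size >= 2:
                hits += sm.J[np.ix_(sel, sel)].sum()
                tot += sel.size * (sel.size - 1)
        occ = sp_occupancy(K, params, f)
        se = np.sqrt(occ.g_plus * (1 - occ.g_plus) / tot)
        assert abs(hits / tot - occ.g_plus) < 4 * se


class TestMPRule:
    def test_zero_presentations_leave_matrix(self):
        ps = generate_prototypes(100, 5, f=0.1, seed=1)
        J0 = stationary_init(100, 0.3, np.random.default_rng(2))
        out = learn_mp(ps, PlasticityParams(q_plus=0.5, g_ratio=1.0), 0, seed=3, init=J0)
        assert np.array_equal(out.J, J0)

    def test_willshaw_limit_exact(self):
        """x=0, no depression, q_plus=1 from zero reproduces Willshaw exactly."""
        ps = generate_prototypes(120, 8, f=0.1, seed=3)
        wm = learn_willshaw(ps)
        mp = learn_mp(ps, PlasticityParams(q_plus=1.0, g_ratio=0.0, noise_x=0.0),
                      3000, seed=9, init="zero")
        assert np.array_equal(wm.J, mp.J)

    def test_occupancy_against_simulation(self):
        """Slow-learning stationary occupancies match long learn_mp runs,
        averaged over prototype realisations."""
        N, P, f = 250, 12, 0.06
        params = PlasticityParams(q_plus=0.03, g_ratio=1.0, noise_x=0.2)
        occ = mp_occupancy_finite(params, f, P)
        gp_reps, gm_reps = [], []
        for rep in range(8):
            protos = generate_prototypes(N, P, f=f, seed=40 + rep)
            sm = learn_mp(protos, params, 25_000, seed=140 + rep, init="stationary")
            hp = tp = hm = tm = 0
            for mu in range(P):
                sel = protos.selective_indices(mu)
                nsel = np.setdiff1d(np.arange(N), sel)[:60]
                if sel.size >= 2:
                    hp += sm.J[np.ix_(sel, sel)].sum()
                    tp += sel.size * (sel.size - 1)
                hm += sm.J[np.ix_(nsel, sel)].sum()
                tm += nsel.size * sel.size
            gp_reps.append(hp / tp)
            gm_reps.append(hm / tm)
        for emp, theory in ((gp_reps, occ.g_plus), (gm_reps, occ.g_minus)):
            emp = np.array(emp)
            se = emp.std(ddof=1) / np.sqrt(len(emp))
            assert abs(emp.mean() - theory) < 4 * max(se, 1e-3), (emp.mean(), theory)

    def test_occupancy_limits(self):
        # x = 1: presentations carry no prototype information
        occ = mp_occupancy(PlasticityParams(q_plus=1.0, g_ratio=1.0, noise_x=1.0), omega=0.5)
        assert occ.g_plus == pytest.approx(occ.g_minus, abs=1e-12)
        # g -> 0, x = 0: Willshaw occupancies at matched load
        occ = mp_occupancy(PlasticityParams(q_plus=1.0, g_ratio=0.0, noise_x=0.0), omega=0.7)
        assert occ.g_plus == 1.0
        assert occ.g_minus == pytest.approx(1 - np.exp(-0.7), abs=1e-10)

    def test_occupancy_monotone_in_noise(self):
        gps = [mp_occupancy(PlasticityParams(q_plus=1.0, g_ratio=1.0, noise_x=x),
                            omega=0.5).g_plus
               for x in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)]
        assert all(a >= b - 1e-12 for a, b in zip(gps, gps[1:]))

    def test_asymptotic_matches_finite_for_sparse_coding(self):
        """The Poisson-mixture form is the sparse limit of the exact
        finite-(P, f) enumeration."""
        params = PlasticityParams(q_plus=0.01, g_ratio=1.0, noise_x=0.3)
        omega = 0.32
        asym = mp_occupancy(params, omega=omega)
        for f, tol in ((0.02, 0.05), (0.005, 0.02)):
            P = round(omega / f**2)
            fin = mp_occupancy_finite(params, f, P)
            assert fin.g_plus == pytest.approx(asym.g_plus, abs=tol)
            assert fin.g_minus == pytest.approx(asym.g_minus, abs=tol)


class TestSynapticMatrixIO:
    def test_roundtrip_and_diagonal(self, tmp_path):
        rng = np.random.default_rng(1)
        J = (rng.random((70, 70)) < 0.3).astype(np.uint8)
        sm = SynapticMatrix(J=J, rule="sp", provenance={"q_plus": 0.5})
        assert np.diagonal(sm.J).sum() == 0
        sm.save(tmp_path / "mat")
        back = SynapticMatrix.load(tmp_path / "mat")
        assert np.array_equal(back.J, sm.J)
        assert back.rule == "sp" and back.provenance["q_plus"] == 0.5
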