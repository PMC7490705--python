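"""Mean-field establishment simulator: recurrence, stochastic mode, sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedflux.establishment import (SimConfig, TaxonLifeHistory, Trajectory,
                                    run_replicates, run_sweep,
                                    simulate_establishment, stage_flow_report)


def reference_recurrence(n, e, g, v, f, s, years):
    """Independent hand-rolled expectation recurrence (oracle)."""
    out, state = [], 0.0
    for year in range(1, years + 1):
        pool = n * e if year == 1 else state * f
        state = min(s, state + min(s - state, pool * g * v))
        out.append(state)
    return out


class TestDeterministic:
    def test_no_influx_stays_empty(self):
        life = TaxonLifeHistory("t", 0.5, 0.5, 100)
        for cfg in (SimConfig(influx=0, escape_rate=0.1),
                    SimConfig(influx=1000, escape_rate=0.0)):
            traj, _ = simulate_establishment(cfg, life)
            assert (traj.invaded == 0).all()
            assert traj.fully_established_year is None

    def test_saturation_from_year_one(self):
        life = TaxonLifeHistory("t", 1.0, 1.0, 10)
        cfg = SimConfig(influx=5000, escape_rate=1.0, sites=1000)
        traj, _ = simulate_establishment(cfg, life)
        assert (traj.invaded == 1000).all()
        assert traj.fully_established_year == 1

    def test_reed_like_recurrence_hand_arithmetic(self):
        # year 1: 9898 * 0.01 * 0.26 * 0.10 = 2.573; year 2 grows by
        # f*g*v = 9500*0.026 = 247 offspring sites per invaded site
        life = TaxonLifeHistory("reed", 0.26, 0.10, 9500)
        cfg = SimConfig(influx=9898, escape_rate=0.01, sites=1000, years=4)
        traj, _ = simulate_establishment(cfg, life)
        assert traj.invaded[0] == pytest.approx(2.57348)
        assert traj.invaded[1] == pytest.approx(2.57348 * (1 + 247), rel=1e-9)
        assert traj.invaded[2] == 1000.0  # capped
        np.testing.assert_allclose(
            traj.invaded,
            reference_recurrence(9898, 0.01, 0.26, 0.10, 9500, 1000, 4))

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(0, 1e5), st.floats(0, 1), st.floats(0, 1),
           st.floats(0, 1), st.floats(1, 1e4), st.integers(1, 2000),
           st.integers(1, 12))
    def test_matches_reference_recurrence(self, n, e, g, v, f, s, years):
        life = TaxonLifeHistory("h", g, v, f)
        cfg = SimConfig(influx=n, escape_rate=e, sites=s, years=years)
        traj, _ = simulate_establishment(cfg, life)
        np.testing.assert_allclose(
            traj.invaded, reference_recurrence(n, e, g, v, f, s, years),
            rtol=1e-9, atol=1e-12)
        # trajectory invariants: non-decreasing and bounded by S
        assert (np.diff(traj.invaded) >= -1e-9).all()
        assert (traj.invaded <= s + 1e-9).all()

    def test_monotone_in_every_parameter(self):
        base = dict(n=5000, e=0.002, g=0.2, v=0.3, f=50)

        def year4(n, e, g, v, f):
            life = TaxonLifeHistory("m", g, v, f)
            cfg = SimConfig(influx=n, escape_rate=e, sites=1000, years=4)
            traj, _ = simulate_establishment(cfg, life)
            return traj.invaded_after(4)

        for key, grid in [("n", [0, 100, 5000, 50000]),
                          ("e", [0.0001, 0.001, 0.01, 0.1]),
                          ("g", [0.05, 0.2, 0.8]),
                          ("v", [0.05, 0.3, 0.9]),
                          ("f", [1, 50, 5000])]:
            vals = [year4(**{**base, key: x}) for x in grid]
            assert vals == sorted(vals), f"not monotone in {key}"

    def test_collision_correction_never_exceeds_cap(self):
        life = TaxonLifeHistory("t", 0.3, 0.3, 200)
        plain = SimConfig(influx=10000, escape_rate=0.01, years=6)
        corr = SimConfig(influx=10000, escape_rate=0.01, years=6,
                         collision_correction=True)
        t_plain, _ = simulate_establishment(plain, life)
        t_corr, _ = simulate_establishment(corr, life)
        assert (t_corr.invaded <= t_plain.invaded + 1e-9).all()
        # in the sparse first year the two agree closely
        assert t_corr.invaded[0] == pytest.approx(t_plain.invaded[0], rel=0.01)


class TestStageFlow:
    def test_escape_multiplication(self):
        life = TaxonLifeHistory("t", 0.5, 0.5, 10)
        cfg = SimConfig(influx=1000, escape_rate=0.01, years=1)
        _, flow = simulate_establishment(cfg, life)
        assert flow.loc[0, "seeds_escaped"] == pytest.approx(10.0)

    def test_cane_like_chain_hand_arithmetic(self):
        life = TaxonLifeHistory("cane", 0.09, 0.47, 2000)
        cfg = SimConfig(influx=17375, escape_rate=0.01, years=3)
        _, flow = simulate_establishment(cfg, life)
        y1 = flow.iloc[0]
        assert y1["seeds_escaped"] == pytest.approx(173.75)
        assert y1["germinated"] == pytest.approx(15.6375)
        assert y1["survived"] == pytest.approx(7.349625)
        assert y1["seeds_reproduced"] == pytest.approx(7.349625 * 2000)

    def test_stage_ordering_on_stochastic_replicate(self):
        life = TaxonLifeHistory("t", 0.4, 0.6, 30)
        cfg = SimConfig(influx=5000, escape_rate=0.05, years=6,
                        mode="stochastic", rng_seed=5)
        _, flow = simulate_establishment(cfg, life)
        assert (flow["seeds_escaped"] <= flow["seeds_influx"]).all()
        assert (flow["germinated"] <= flow["seeds_escaped"]).all()
        assert (flow["survived"] <= flow["germinated"]).all()
        assert (flow["seeds_reproduced"] ==
                flow["invaded_sites"] * 30).all()

    def test_report_covers_all_taxon_season_cells(self):
        lifes = {"a": TaxonLifeHistory("a", 0.2, 0.5, 100),
                 "b": TaxonLifeHistory("b", 0.1, 0.9, 1000)}
        influxes = {("a", "s1"): 500.0, ("a", "s2"): 700.0,
                    ("b", "s1"): 50.0}
        flow = stage_flow_report(lifes, influxes, escape_rate=0.01, years=5)
        assert set(zip(flow["taxon"], flow["season"])) == set(influxes)
        assert (flow["escape_rate"] == 0.01).all()
        assert len(flow) == 3 * 5


class TestStochastic:
    def test_reproducible_given_seed(self):
        life = TaxonLifeHistory("t", 0.3, 0.4, 20)
        cfg = SimConfig(influx=2000, escape_rate=0.01, years=8,
                        mode="stochastic", replicates=5, rng_seed=123)
        a = run_replicates(cfg, life)
        b = run_replicates(cfg, life)
        np.testing.assert_array_equal(a, b)
        assert (np.diff(a, axis=1) >= 0).all()
        assert (a <= cfg.sites).all()

    def test_extinction_fraction_matches_poisson_thinning(self):
        # year-1 founders ~ Binomial(N, e*g*v); extinction iff zero founders
        n, e, g, v = 1000, 0.001, 0.5, 0.5
        lam = n * e * g * v  # 0.25 expected founders
        life = TaxonLifeHistory("t", g, v, 50)
        cfg = SimConfig(influx=n, escape_rate=e, years=10, mode="stochastic",
                        replicates=600, rng_seed=17)
        final = run_replicates(cfg, life)[:, -1]
        p0_hat = float((final == 0).mean())
        p0 = np.exp(-lam)
        se = np.sqrt(p0 * (1 - p0) / cfg.replicates)
        assert abs(p0_hat - p0) < 3 * se + abs((1 - e * g * v) ** n - p0)

    def test_mean_matches_deterministic_when_collision_free(self):
        # doubling regime far below carrying capacity: means should agree
        g, v, f = 0.5, 0.4, 5
        life = TaxonLifeHistory("t", g, v, f)
        cfg = SimConfig(influx=2000, escape_rate=0.01, sites=10_000, years=5,
                        mode="stochastic", replicates=600, rng_seed=29)
        ens = run_replicates(cfg, life)
        det, _ = simulate_establishment(
            SimConfig(influx=2000, escape_rate=0.01, sites=10_000, years=5),
            life)
        mean5 = ens[:, -1].mean()
        se = ens[:, -1].std(ddof=1) / np.sqrt(cfg.replicates)
        assert abs(mean5 - det.invaded[-1]) < 3 * se


class TestSweep:
    LIFES = {"cane": TaxonLifeHistory("cane", 0.09, 0.47, 2000),
             "cattail": TaxonLifeHistory("cattail", 0.18, 0.91, 250_000)}
    INFLUX = {("cane", "s1"): 24_065.0, ("cattail", "s1"): 68.0}

    def test_zero_escape_reports_zero_everywhere(self):
        sweep = run_sweep(self.LIFES, self.INFLUX, e_grid=[0.0],
                          v_grid=[0.1, "empirical"], s_values=(100,), years=4)
        assert (sweep["invaded_after_4y"] == 0).all()
        assert not sweep["fully_established"].any()

    def test_site_count_speeds_up_but_does_not_change_outcome(self):
        sweep = run_sweep(self.LIFES, self.INFLUX,
                          e_grid=[0.001, 0.005, 0.05],
                          v_grid=[0.10], s_values=(1000, 100), years=10)
        wide = sweep.pivot_table(index=["taxon", "escape_rate"],
                                 columns="sites",
                                 values=["fully_established",
                                         "fully_established_year"],
                                 aggfunc="first")
        est = wide["fully_established"]
        assert (est[100] == est[1000]).all()
        both = wide["fully_established_year"].dropna()
        assert (both[100] <= both[1000]).all()
        assert est.any(axis=None)  # sweep covers at least one establishing cell

    def test_scarce_taxon_invades_less_than_abundant_one(self):
        lifes = {"cattail": TaxonLifeHistory("cattail", 0.18, 0.10, 100),
                 "cane": TaxonLifeHistory("cane", 0.09, 0.10, 100)}
        influx = {("cattail", "s1"): 68.0, ("cane", "s1"): 24_065.0}
        sweep = run_sweep(lifes, influx, e_grid=[0.005], v_grid=[0.10],
                          s_values=(1000,), years=4)
        by_taxon = sweep.set_index("taxon")["invaded_after_4y"]
        assert by_taxon["cattail"] < by_taxon["cane"]

    def test_empirical_survival_resolves_and_flags(self):
        sweep = run_sweep(self.LIFES, self.INFLUX, e_grid=[0.01],
                          v_grid=[0.05, 0.50, "empirical"], s_values=(100,),
                          years=4)
        cane = sweep[sweep["taxon"] == "cane"]
        assert 0.47 in cane["v_used"].values
        flagged = cane.loc[cane["v_used"] == 0.50, "v_above_empirical"]
        assert flagged.all()
        assert not cane.loc[cane["v_used"] == 0.47,
                            "v_above_empirical"].any()


class TestValidation:
    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(influx=-1, escape_rate=0.1)
        with pytest.raises(ValueError):
            SimConfig(influx=1, escape_rate=1.5)
        with pytest.raises(ValueError):
            SimConfig(influx=1, escape_rate=0.1, mode="hybrid")
        with pytest.raises(ValueError):
            TaxonLifeHistory("t", 1.2, 0.5, 10)
        with pytest.raises(ValueError):
            TaxonLifeHistory("t", 0.5, 0.5, 0)

    def test_trajectory_records_first_full_year(self):
        t = Trajectory(np.array([1.0, 50.0, 100.0, 100.0]), sites=100)
        assert t.fully_established_year == 3
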