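"""Cohort simulator: growth curve, annual step, trajectories, recovery."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arborcarbon.growth import (
    Cohort,
    GrowthParams,
    ManagementRegime,
    density_trajectory,
    fit_growth_curve,
    spin_up,
    stem_volume,
    step_cohort,
    step_cohort_with_fluxes,
)
from arborcarbon.parameters import ORGANS


def make_params(**overrides):
    base = dict(
        v_max=300.0,
        k=0.05,
        m=2.0,
        wood_density=0.45,
        organ_share={"stem": 0.62, "root": 0.20, "foliage": 0.06, "branch": 0.12},
        turnover={"foliage": 0.25, "branch": 0.03, "root": 0.04},
        mortality=0.005,
    )
    base.update(overrides)
    return GrowthParams(**base)


#: With k=1, exp(-k*age) underflows below float resolution by age 40, so
#: the volume increment is exactly zero: a stand with no growth.
STATIC = dict(
    k=1.0,
    m=1.0,
    turnover={"foliage": 0.0, "branch": 0.0, "root": 0.0},
    mortality=0.0,
)


def make_cohort(pools=None, area=1.0, age=40, forest_class="commercial"):
    pools = pools or {o: 0.0 for o in ORGANS}
    return Cohort("X", forest_class, area, age, {o: pools.get(o, 0.0) for o in ORGANS})


class TestStemVolume:
    def test_zero_at_age_zero(self):
        assert stem_volume(0, make_params()) == 0.0

    def test_chapman_richards_value(self):
        p = make_params(v_max=300.0, k=0.05, m=2.0)
        assert stem_volume(20, p) == pytest.approx(300.0 * (1 - math.exp(-1.0)) ** 2)
        assert stem_volume(20, p) == pytest.approx(119.87, abs=0.005)

    def test_approaches_asymptote(self):
        p = make_params(m=1.0)
        assert stem_volume(10.0 / p.k, p) == pytest.approx(p.v_max, abs=0.005 * p.v_max)

    def test_monotone_nondecreasing(self):
        p = make_params()
        vols = [stem_volume(a, p) for a in range(0, 200)]
        assert all(b >= a for a, b in zip(vols, vols[1:]))

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            stem_volume(-1, make_params())


class TestStepCohort:
    def test_public_welfare_step_never_harvests(self):
        c = make_cohort({"stem": 30.0, "root": 9.0}, forest_class="public_welfare", age=5)
        _, flow = step_cohort(c, make_params(), ManagementRegime.unmanaged())
        assert flow.stemwood_carbon == 0.0 and flow.residue_carbon == 0.0

    def test_all_rates_zero_is_identity(self):
        c = make_cohort({"stem": 10.0, "root": 2.0, "foliage": 1.0, "branch": 0.5})
        c2, flow = step_cohort(c, make_params(**STATIC), ManagementRegime.unmanaged())
        assert dict(c2.pools) == dict(c.pools)
        assert flow.total == 0.0

    def test_rotation_residue_split(self):
        # stem pool 10 MgC/ha on 1 Mha, clear-fell, residue fraction 0.4
        c = make_cohort({"stem": 10.0}, area=1.0, age=40)
        regime = ManagementRegime(rotation_years=41, residue_fraction=0.4)
        c2, flow = step_cohort(c, make_params(**STATIC), regime)
        assert flow.residue_carbon == pytest.approx(4.0)
        assert flow.stemwood_carbon == pytest.approx(6.0)
        assert c2.age == 0 and c2.density == 0.0

    def test_thinning_removes_stated_fraction(self):
        c = make_cohort({o: 8.0 for o in ORGANS}, age=40)
        regime = ManagementRegime(rotation_years=60, thinnings=((41, 0.25),))
        c2, flow = step_cohort(c, make_params(**STATIC), regime)
        assert flow.total == pytest.approx(0.25 * 4 * 8.0)
        assert c2.density == pytest.approx(0.75 * 4 * 8.0)
        assert c2.age == 41  # thinning does not reset the stand

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        age=st.integers(0, 80),
        stem=st.floats(0.0, 200.0),
        soft=st.floats(0.0, 40.0),
        mortality=st.floats(0.0, 0.05),
        rotation=st.integers(5, 60),
    )
    def test_carbon_balance_to_1e9(self, age, stem, soft, mortality, rotation):
        """Each step conserves carbon: dC = increment - turnover - mortality - harvest."""
        p = make_params(mortality=mortality)
        c = make_cohort({"stem": stem, "root": soft, "foliage": soft / 2, "branch": soft / 3},
                        area=2.5, age=age)
        regime = ManagementRegime(rotation_years=rotation, thinnings=((max(1, rotation // 2), 0.2),))
        c2, flow, fx = step_cohort_with_fluxes(c, p, regime)
        lhs = c2.stock - c.stock
        rhs = fx.increment - fx.turnover - fx.mortality - fx.harvest
        assert lhs == pytest.approx(rhs, abs=1e-9 * max(1.0, abs(c.stock)))
        assert flow.total == pytest.approx(fx.harvest, abs=1e-12)

    def test_harvest_periodic_under_uniform_age_structure(self):
        """With a uniform age structure the national harvest cycles with the rotation."""
        p = make_params(v_max=200.0, k=0.08)
        rotation = 10
        regime = ManagementRegime(rotation_years=rotation, residue_fraction=0.4)
        cohorts = [
            spin_up("X", "commercial", 0.1, age, p, regime) for age in range(rotation)
        ]
        harvest = []
        for _ in range(4 * rotation):
            total = 0.0
            nxt = []
            for c in cohorts:
                c, flow = step_cohort(c, p, regime)
                total += flow.total
                nxt.append(c)
            cohorts = nxt
            harvest.append(total)
        for t in range(rotation + 1, 3 * rotation):
            assert harvest[t + rotation] == pytest.approx(harvest[t], rel=1e-9)


class TestDensityTrajectory:
    def test_single_cohort_equals_pool_total(self):
        p = make_params()
        regime = ManagementRegime.unmanaged()
        traj = density_trajectory("X", p, regime, {12: 3.0}, years=range(2018, 2024))
        ref = spin_up("X", "pw", 3.0, 12, p, regime)
        assert traj.loc[2018] == pytest.approx(ref.density)
        for year in range(2019, 2024):
            ref, _ = step_cohort(ref, p, regime)
            assert traj.loc[year] == pytest.approx(ref.density)

    def test_unmanaged_growth_nondecreasing_while_increment_dominates(self):
        p = make_params()
        c = spin_up("X", "pw", 1.0, 5, p, ManagementRegime.unmanaged())
        for _ in range(80):
            c2, _, fx = step_cohort_with_fluxes(c, p, ManagementRegime.unmanaged())
            if fx.increment > fx.turnover + fx.mortality:
                assert c2.density >= c.density
            c = c2

    def test_empty_age_structure_rejected(self):
        with pytest.raises(ValueError):
            density_trajectory("X", make_params(), ManagementRegime.unmanaged(), {})


class TestParameterRecovery:
    def test_vmax_k_recovered_from_noiseless_series(self):
        p = make_params(v_max=412.7, k=0.043, m=2.2)
        ages = list(range(1, 61))
        volumes = [stem_volume(a, p) for a in ages]
        v_max, k = fit_growth_curve(ages, volumes, m=p.m)
        assert v_max == pytest.approx(p.v_max, rel=1e-6)
        assert k == pytest.approx(p.k, rel=1e-6)
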