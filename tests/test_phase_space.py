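"""Phase-space classification tests: region labels, symbiosis types,
synergy, boundary handling, the unbalanced-HGT variant and the grid map."""

import numpy as np
import pytest
from scipy import ndimage

from hgtosc import (
    InducedPayoffs,
    ModelParams,
    classify_fixed,
    classify_region,
    classify_region_unbalanced,
    region_map,
    synergy_flag,
)


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "payoffs, region, symbiosis, synergy",
        [
            (InducedPayoffs(-0.01, -0.08), "I", "pure_competition", False),
            (InducedPayoffs(0.08, -0.08), "II", "pure_competition", True),
            (InducedPayoffs(0.11, -0.11), "III", "mutualism", True),
            (InducedPayoffs(0.05, 0.02), "IV", "not_applicable", False),
            (InducedPayoffs(-0.15, 0.05), "V", "not_applicable", False),
            (InducedPayoffs(-0.15, -0.08), "VI", "not_applicable", False),
            (InducedPayoffs(0.2, -0.3), "NA", "not_applicable", False),
        ],
    )
    def test_reference_points(self, ref_params, payoffs, region, symbiosis, synergy):
        res = classify_region(ref_params, payoffs)
        assert res.region == region
        assert res.symbiosis == symbiosis
        assert res.synergy == synergy

    def test_zero_payoffs_reduce_to_fixed_environment(self, ref_params):
        res = classify_region(ref_params, InducedPayoffs(0.0, 0.0))
        assert res.region == "IV"  # r_A > r_B: A wins, as in the fixed environment

    def test_parasitism_subregions(self, ref_params):
        # region I with kappa < -a: B parasitises A
        res = classify_region(ref_params, InducedPayoffs(-0.01, -0.15))
        assert res.region == "I"
        assert res.symbiosis == "parasitism_B_on_A"
        # region III with xi > a but kappa > -a: A parasitises B
        res = classify_region(ref_params, InducedPayoffs(0.15, -0.08))
        assert res.region == "III"
        assert res.symbiosis == "parasitism_A_on_B"

    def test_coexistence_regions_carry_interior_equilibrium(self, ref_params):
        for payoffs in [InducedPayoffs(-0.01, -0.08), InducedPayoffs(0.11, -0.11)]:
            res = classify_region(ref_params, payoffs)
            assert res.equilibrium is not None
            assert 0.0 < res.equilibrium.p_A_star < 1.0
            assert res.equilibrium.N_star > 0.0

    def test_points_on_decision_lines_labelled_boundary(self, ref_params):
        kappa_thr = 0.1 * (1.0 / 1.8 - 1.0)
        assert classify_region(ref_params, InducedPayoffs(0.05, kappa_thr)).region == "boundary"
        assert classify_region(ref_params, InducedPayoffs(0.1, -0.08)).region == "boundary"
        assert classify_region(ref_params, InducedPayoffs(0.0, -0.08)).region == "boundary"

    def test_nonzero_gamma_rejected(self, ref_params):
        with pytest.raises(ValueError, match="gamma"):
            classify_region(ref_params.replace(gamma=0.01), InducedPayoffs(0.0, 0.0))

    def test_unequal_competition_rejected(self):
        params = ModelParams(1.8, 1.0, 0.1, 0.05, 0.1, 0.1)
        with pytest.raises(ValueError, match="equal competition"):
            classify_region(params, InducedPayoffs(0.0, 0.0))


class TestSynergy:
    def test_synergetic_point(self, ref_params):
        flag, N_c, N_f = synergy_flag(ref_params, InducedPayoffs(0.08, -0.08))
        assert flag
        assert N_c == pytest.approx(70.0 / 3.0, rel=1e-10)
        assert N_f == pytest.approx(18.0)

    def test_non_synergetic_point(self, ref_params):
        flag, N_c, N_f = synergy_flag(ref_params, InducedPayoffs(-0.01, -0.08))
        assert not flag
        assert N_c < N_f

    def test_xi_zero_gives_equal_abundances_no_synergy(self, ref_params):
        flag, N_c, N_f = synergy_flag(ref_params, InducedPayoffs(0.0, -0.08))
        assert N_c == pytest.approx(N_f, rel=1e-12)
        assert not flag  # strict inequality


class TestUnbalanced:
    def test_zero_payoffs_match_fixed_classification(self, ref_params):
        # inside the fixed-environment coexistence interval
        params = ref_params.replace(gamma=-0.06)
        res = classify_region_unbalanced(params, InducedPayoffs(0.0, 0.0))
        assert res.region in ("I", "II", "III")  # coexistence
        fixed = classify_fixed(params)
        interior = next(e for e in fixed.equilibria if e.label == "interior")
        assert res.equilibrium.p_A_star == pytest.approx(interior.p_A_star, rel=1e-10)
        # outside the interval: exclusion, matching the fixed outcome
        params = ref_params.replace(gamma=0.05)
        res = classify_region_unbalanced(params, InducedPayoffs(0.0, 0.0))
        assert res.region == "IV"
        assert classify_fixed(params).outcome == "A_wins"

    def test_oscillations_destroy_fixed_coexistence(self, ref_params):
        params = ref_params.replace(gamma=-0.06)
        res = classify_region_unbalanced(params, InducedPayoffs(-0.05, 0.03))
        assert res.region not in ("I", "II", "III")
        assert res.coexistence_destroyed
        # gamma+kappa = -0.03 > -0.0444 makes A-only stable; gamma+xi = -0.11
        # < -0.08 makes B-only stable too, so the outcome is bistable
        assert res.region == "V"

    def test_oscillations_shift_coexistence_composition(self, ref_params):
        params = ref_params.replace(gamma=-0.06)
        base = classify_region_unbalanced(params, InducedPayoffs(0.0, 0.0))
        shifted = classify_region_unbalanced(params, InducedPayoffs(0.02, -0.01))
        assert shifted.region in ("I", "II", "III")
        assert shifted.equilibrium.p_A_star != pytest.approx(
            base.equilibrium.p_A_star, abs=1e-6
        )


@pytest.fixture(scope="module")
def coarse_map():
    params = ModelParams.symmetric(1.8, 1.0, 0.1)
    return region_map(params, extent=0.3, step=0.02)


class TestRegionMap:

    def test_all_labels_present(self, coarse_map):
        assert {"I", "II", "III", "IV", "V", "VI", "NA"} <= set(coarse_map.region)

    def test_single_node_grid(self, ref_params):
        df = region_map(ref_params, xi_values=np.array([0.08]), kappa_values=np.array([-0.08]))
        assert len(df) == 1
        assert df.region.iloc[0] == "II"

    def test_coexistence_subregions_partition(self, coarse_map):
        coexist = coarse_map[coarse_map.region.isin(["I", "II", "III"])]
        assert coexist.p_A_star.between(0, 1).all()
        # sub-region labels are disjoint by construction; verify exhaustiveness:
        # every grid node satisfying the coexistence conditions is labelled I/II/III
        a, rA, rB = 0.1, 1.8, 1.0
        df = coarse_map
        cond = (
            (df.kappa < a * (rB / rA - 1))
            & (df.xi > a * (1 - rA / rB))
            & (a * (df.xi - df.kappa) + df.xi * df.kappa > 0)
        )
        assert set(df.loc[cond, "region"]) <= {"I", "II", "III", "boundary"}

    def test_regions_connected(self, coarse_map):
        n_xi = coarse_map.xi.nunique()
        n_kappa = coarse_map.kappa.nunique()
        for label in ["I", "II", "III", "IV", "V", "VI", "NA"]:
            mask = (coarse_map.region == label).to_numpy().reshape(n_kappa, n_xi)
            _, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))
            assert n_comp == 1, f"region {label} fragmented into {n_comp} components"

    def test_abundance_increases_with_xi_at_fixed_kappa(self, ref_params):
        kappa = -0.08
        xis = np.linspace(-0.05, 0.25, 31)
        N = []
        for xi in xis:
            res = classify_region(ref_params, InducedPayoffs(float(xi), kappa))
            if res.region in ("I", "II", "III"):
                N.append(res.equilibrium.N_star)
        assert len(N) > 10
        assert np.all(np.diff(N) > 0)
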