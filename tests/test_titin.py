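"""Serial titin chain: equal-force solves vs an independent oracle,
binding, the calcium parameter set and the structural anchors."""

import numpy as np
import pytest
from scipy.optimize import brentq

from trifilament.polymer import ewlc_extension, wlc_extension, wlc_force, ewlc_force
from trifilament.titin import (
    CALCIUM_REFERENCE_HSL,
    TitinStrandState,
    actin_extension,
    apply_calcium,
    bind_to_actin,
    chain_force,
    chain_force_vec,
    default_isoform,
    slack_length,
    unbind_from_actin,
)


def oracle_chain_force(hsl, isoform, n_unfolded=0, bound=False, frozen=0.0, tol=1e-10):
    """Independent oracle: brentq on force, summing inverse extensions of
    each compartment separately (not the aggregated-contour shortcut)."""

    def total_length(f):
        x = isoform.half_a_band_length + f / isoform.a_band_stiffness
        x += isoform.distal_end_filament_length
        x += ewlc_extension(f, isoform.pevk)
        if bound:
            x += frozen
        else:
            for _ in range(isoform.n_proximal_ig - n_unfolded):
                x += wlc_extension(f, isoform.folded_ig)
            for _ in range(n_unfolded):
                x += wlc_extension(f, isoform.unfolded_ig)
        return x

    if total_length(1e-9) >= hsl:
        return 0.0
    hi = 1.0
    while total_length(hi) < hsl:
        hi *= 2
    return brentq(lambda f: total_length(f) - hsl, 0.0, hi, rtol=tol)


class TestIsoformAnchors:
    def test_unfolding_contour_gain_is_26nm(self, isoform):
        gain = isoform.unfolded_ig.contour_length - isoform.folded_ig.contour_length
        assert gain == pytest.approx(26.0, abs=1e-12)

    def test_folded_ig_contour(self, isoform):
        assert isoform.folded_ig.contour_length == 4.5

    def test_pevk_contour_per_residue(self, isoform):
        assert isoform.pevk.contour_length / isoform.n_pevk_residues == (
            pytest.approx(0.36, abs=1e-12)
        )

    def test_domain_and_residue_counts(self, isoform):
        assert isoform.n_proximal_ig == 50
        assert isoform.n_distal_ig == 26
        assert isoform.n_pevk_residues == 800

    def test_invariants_enforced(self, isoform):
        from dataclasses import replace
        from trifilament.polymer import WLCParams

        with pytest.raises(ValueError):
            replace(isoform, unfolded_ig=WLCParams(0.8, 40.0))
        with pytest.raises(ValueError):
            replace(isoform, n_pevk_residues=700)  # breaks PEVK contour link
        with pytest.raises(ValueError):
            replace(isoform, n_proximal_ig=0)


class TestSlackLength:
    def test_force_is_zero_at_slack(self, isoform, strand_state):
        s = slack_length(isoform, strand_state)
        assert chain_force(s, isoform, strand_state).common_force == 0.0

    def test_just_above_slack_force_positive(self, isoform, strand_state):
        s = slack_length(isoform, strand_state)
        assert chain_force(s + 1.0, isoform, strand_state).common_force > 0

    def test_tracks_epsilon_force_convention_across_unfolding(self, isoform):
        # under the infinitesimal-force rest convention, slack for any
        # composition equals rigid offset + per-compartment eps-extensions
        # (note: with entropic springs the contour gain of unfolding does
        # NOT necessarily lengthen the eps-force configuration)
        eps = 1e-6
        for k in (0, 5, 20, 50):
            state = TitinStrandState(n_unfolded=k)
            expected = (
                isoform.rigid_offset
                + eps / isoform.a_band_stiffness
                + (50 - k) * wlc_extension(eps, isoform.folded_ig)
                + k * wlc_extension(eps, isoform.unfolded_ig)
                + ewlc_extension(eps, isoform.pevk)
            )
            assert slack_length(isoform, state) == pytest.approx(expected, abs=1e-9)

    def test_numeric_value_from_zero_force_convention(self, isoform, strand_state):
        # rigid offset + epsilon-force extensions evaluated directly
        eps = 1e-6
        expected = (
            isoform.half_a_band_length
            + eps / isoform.a_band_stiffness
            + isoform.distal_end_filament_length
            + 50 * wlc_extension(eps, isoform.folded_ig)
            + ewlc_extension(eps, isoform.pevk)
        )
        assert slack_length(isoform, strand_state) == pytest.approx(
            expected, abs=1e-9
        )


class TestChainForce:
    def test_at_slack_zero(self, isoform, strand_state):
        s = slack_length(isoform, strand_state)
        sol = chain_force(s, isoform, strand_state)
        assert sol.common_force == 0.0

    def test_monotone_in_length(self, isoform, strand_state):
        hsls = np.linspace(950.0, 2200.0, 25)
        forces = [
            chain_force(h, isoform, strand_state).common_force for h in hsls
        ]
        above = [f for f in forces if f > 0]
        assert all(b > a for a, b in zip(above, above[1:]))

    def test_oracle_default_case(self, isoform):
        state = TitinStrandState(n_unfolded=10)
        got = chain_force(1500.0, isoform, state).common_force
        assert got == pytest.approx(
            oracle_chain_force(1500.0, isoform, n_unfolded=10), rel=1e-9
        )

    def test_oracle_on_100_random_instances(self, isoform):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_u = int(rng.integers(0, 51))
            state = TitinStrandState(n_unfolded=n_u)
            hsl = float(rng.uniform(1000.0, 2600.0))
            got = chain_force(hsl, isoform, state).common_force
            want = oracle_chain_force(hsl, isoform, n_unfolded=n_u)
            assert got == pytest.approx(want, rel=1e-6, abs=1e-9)

    def test_length_sum_invariant(self, isoform):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n_u = int(rng.integers(0, 51))
            hsl = float(rng.uniform(950.0, 2600.0))
            sol = chain_force(hsl, isoform, TitinStrandState(n_unfolded=n_u))
            assert sol.total_length == pytest.approx(hsl, abs=1e-6)

    def test_equal_force_invariant(self, isoform):
        sol = chain_force(1800.0, isoform, TitinStrandState(n_unfolded=15))
        f = sol.common_force
        # evaluate every compartment's own force law at its solved length
        assert wlc_force(sol.folded_ig_each, isoform.folded_ig) == pytest.approx(
            f, rel=1e-8
        )
        assert wlc_force(sol.unfolded_ig_each, isoform.unfolded_ig) == (
            pytest.approx(f, rel=1e-8)
        )
        assert ewlc_force(sol.pevk_length, isoform.pevk) == pytest.approx(
            f, rel=1e-8
        )
        aband_ext = sol.a_band_length - isoform.half_a_band_length
        assert aband_ext * isoform.a_band_stiffness == pytest.approx(f, rel=1e-8)

    def test_force_non_increasing_in_unfolded_count(self, isoform):
        hsl = 1700.0
        forces = [
            chain_force(hsl, isoform, TitinStrandState(n_unfolded=k)).common_force
            for k in range(0, 51, 5)
        ]
        assert all(b <= a for a, b in zip(forces, forces[1:]))

    def test_below_slack_lengths_still_sum(self, isoform, strand_state):
        hsl = 0.5 * (isoform.rigid_offset + slack_length(isoform, strand_state))
        sol = chain_force(hsl, isoform, strand_state)
        assert sol.common_force == 0.0
        assert sol.total_length == pytest.approx(hsl, abs=1e-6)

    def test_invalid_length(self, isoform, strand_state):
        with pytest.raises(ValueError):
            chain_force(-5.0, isoform, strand_state)

    def test_vectorised_matches_scalar(self, isoform):
        hsls = np.array([1100.0, 1400.0, 1900.0, 2400.0])
        vec = chain_force_vec(hsls, isoform, 8)
        for h, fv in zip(hsls, vec):
            fs = chain_force(h, isoform, TitinStrandState(n_unfolded=8)).common_force
            assert fv == pytest.approx(fs, rel=1e-10, abs=1e-12)


class TestCalcium:
    def test_force_ratio_at_reference_length(self, isoform, strand_state):
        hi = apply_calcium(isoform)
        low = chain_force(CALCIUM_REFERENCE_HSL, isoform, strand_state).common_force
        high = chain_force(CALCIUM_REFERENCE_HSL, hi, strand_state).common_force
        assert 100 * (high / low - 1) == pytest.approx(25.0, abs=0.5)

    def test_idempotent(self, isoform):
        hi = apply_calcium(isoform)
        assert apply_calcium(hi) is hi

    def test_ratio_above_one_at_every_length_above_slack(self, isoform, strand_state):
        hi = apply_calcium(isoform)
        slack = slack_length(isoform, strand_state)
        for hsl in np.linspace(slack + 5.0, 2400.0, 20):
            low = chain_force(hsl, isoform, strand_state).common_force
            high = chain_force(hsl, hi, strand_state).common_force
            assert high > low


class TestBinding:
    def test_force_continuous_across_binding(self, isoform, strand_state):
        hsl = 1500.0
        sol = chain_force(hsl, isoform, strand_state)
        bound = bind_to_actin(strand_state, sol)
        sol_b = chain_force(hsl, isoform, bound)
        assert sol_b.common_force == pytest.approx(
            sol.common_force, rel=1e-9
        )

    def test_bound_chain_is_stiffer(self, isoform, strand_state):
        hsl = 1400.0
        sol = chain_force(hsl, isoform, strand_state)
        bound = bind_to_actin(strand_state, sol)
        dh = 1.0
        k_unbound = (
            chain_force(hsl + dh, isoform, strand_state).common_force
            - sol.common_force
        ) / dh
        k_bound = (
            chain_force(hsl + dh, isoform, bound).common_force
            - chain_force(hsl, isoform, bound).common_force
        ) / dh
        assert k_bound > k_unbound

    def test_bound_force_dominates_above_binding_length(self, isoform, strand_state):
        hsl0 = 1300.0
        sol = chain_force(hsl0, isoform, strand_state)
        bound = bind_to_actin(strand_state, sol)
        for hsl in np.linspace(hsl0 + 10, 2100.0, 12):
            fb = chain_force(hsl, isoform, bound).common_force
            fu = chain_force(hsl, isoform, strand_state).common_force
            assert fb > fu

    def test_frozen_length_grows_with_binding_length(self, isoform, strand_state):
        frozen_long = bind_to_actin(
            strand_state, chain_force(1700.0, isoform, strand_state)
        ).frozen_proximal_length
        frozen_short = bind_to_actin(
            strand_state, chain_force(1200.0, isoform, strand_state)
        ).frozen_proximal_length
        assert frozen_long > frozen_short

    def test_rebinding_rejected(self, isoform, strand_state):
        bound = bind_to_actin(strand_state, chain_force(1400.0, isoform, strand_state))
        with pytest.raises(ValueError):
            bind_to_actin(bound, chain_force(1400.0, isoform, strand_state))

    def test_binding_requires_activation(self, isoform, strand_state):
        sol = chain_force(1400.0, isoform, strand_state)
        with pytest.raises(ValueError):
            bind_to_actin(strand_state, sol, crossbridges_active=False)

    def test_unbind_round_trip(self, isoform, strand_state):
        bound = bind_to_actin(strand_state, chain_force(1400.0, isoform, strand_state))
        assert unbind_from_actin(bound) == strand_state

    def test_bound_oracle(self, isoform, strand_state):
        sol = chain_force(1250.0, isoform, strand_state)
        bound = bind_to_actin(strand_state, sol)
        got = chain_force(1600.0, isoform, bound).common_force
        want = oracle_chain_force(
            1600.0, isoform, bound=True, frozen=bound.frozen_proximal_length
        )
        assert got == pytest.approx(want, rel=1e-8)

    def test_discrete_site_spacing_rounds_down(self, isoform, strand_state):
        sol = chain_force(1500.0, isoform, strand_state)
        bound = bind_to_actin(strand_state, sol, site_spacing=5.5)
        assert bound.frozen_proximal_length <= sol.proximal_total
        assert bound.frozen_proximal_length % 5.5 == pytest.approx(0.0, abs=1e-9)


class TestActinExtension:
    def test_paper_compliance_value(self):
        assert actin_extension(1.0, 1.0) == pytest.approx(20.0)

    def test_zero(self):
        assert actin_extension(0.0, 123.0) == 0.0

    def test_linearity(self):
        assert actin_extension(2.0, 3.0) == pytest.approx(120.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            actin_extension(-1.0, 1.0)


class TestStrandState:
    def test_bound_requires_frozen_length(self):
        with pytest.raises(ValueError):
            TitinStrandState(actin_bound=True)

    def test_frozen_only_when_bound(self):
        with pytest.raises(ValueError):
            TitinStrandState(frozen_proximal_length=10.0)

    def test_negative_unfolded_rejected(self):
        with pytest.raises(ValueError):
            TitinStrandState(n_unfolded=-1)
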