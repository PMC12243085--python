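import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from snowflake_water.params import StatePoint
from snowflake_water.snowflake import (
    BOND_HB,
    BOND_LJ,
    BOND_NONE,
    GrowthConfig,
    Molecule,
    accept_placement,
    ensemble_list,
    generate_ensemble,
    interaction_lengths,
    noise_sigmas,
    propose_child,
    sample_interaction,
    sample_noise,
)
from snowflake_water.ud_model import Populations

P_REF = 0.19
ALL_HB = Populations(f_HB=1.0, f_LJ=0.0, f_0=0.0, f_s=0.0)


def honeycomb_sq_distances(max_sq: int = 120) -> set[int]:
    """Squared center-to-site distances of an ideal honeycomb (bond = 1).

    With the center on the A sublattice, A sites sit at squared distance
    3(i^2+ij+j^2) and B sites at 3(i^2+ij+j^2)+3i+1 -- all integers.
    """
    allowed = set()
    for i in range(-12, 13):
        for j in range(-12, 13):
            t = 3 * (i * i + i * j + j * j)
            allowed.add(t)
            allowed.add(t + 3 * i + 1)
    return {d for d in allowed if 0 < d <= max_sq}


def hardcore_violations(flake, params, margin=0.05):
    """Pairs closer than sigma_LJ - margin, minus the documented exception
    (soft acceptance of shell >= 2 molecules near the central molecule)."""
    xy = np.column_stack([flake.x, flake.y])
    cut = params.sigma_LJ - margin
    r_lj = params.sigma_LJ * 2 ** (1 / 6)
    d = squareform(pdist(xy))
    bad = []
    n = len(xy)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] >= cut - 1e-12:
                continue
            if i == 0 and flake.shell[j] >= 2 and d[i, j] < r_lj:
                continue  # allowed soft acceptance against the center
            bad.append((i, j, d[i, j]))
    return bad


class TestInteractionLengths:
    def test_closed_forms(self, mb):
        r = interaction_lengths(StatePoint(T=0.19, p=0.19), mb)
        assert r["HB"] == 1.0
        assert r["LJ"] == pytest.approx(0.7 * 2 ** (1 / 6))
        assert r["0"] == pytest.approx(1.0 + 0.7 * 2 ** (1 / 6))


class TestSampling:
    def test_degenerate_interaction_distributions(self, mb, rng):
        all_hb = ALL_HB
        none = Populations(f_HB=0.0, f_LJ=0.0, f_0=1.0, f_s=0.0)
        assert all(sample_interaction(all_hb, rng) == BOND_HB for _ in range(50))
        assert all(sample_interaction(none, rng) == BOND_NONE for _ in range(50))

    def test_interaction_frequencies_match_populations(self, rng):
        pop = Populations(f_HB=0.5, f_LJ=0.3, f_0=0.1, f_s=0.1)  # p_HB = 0.6
        n = 100_000
        draws = np.array([sample_interaction(pop, rng) for _ in range(n)])
        for code, p in ((BOND_HB, 0.6), (BOND_LJ, 0.3), (BOND_NONE, 0.1)):
            freq = np.mean(draws == code)
            assert abs(freq - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_hb_radial_noise_scale(self, mb, rng):
        sp = StatePoint(T=0.2, p=P_REF)
        sig = noise_sigmas(sp, mb)
        assert sig["r_HB"] == pytest.approx(0.65 * math.sqrt(0.2 / 32), rel=1e-12)
        n = 20_000
        zr = np.array([sample_noise(BOND_HB, sp, mb, rng)[0] for _ in range(n)])
        var = zr.var(ddof=1)
        # chi^2 sampling bound on the variance estimate
        assert abs(var - sig["r_HB"] ** 2) < 3 * sig["r_HB"] ** 2 * math.sqrt(2 / (n - 1))

    def test_lj_angular_noise_support(self, mb, rng):
        sp = StatePoint(T=0.3, p=P_REF)
        zth = np.array([sample_noise(BOND_LJ, sp, mb, rng)[1] for _ in range(2000)])
        assert np.all(np.abs(zth) < math.pi / 3)

    def test_noise_vanishes_with_temperature(self, mb):
        cold = noise_sigmas(StatePoint(T=1e-8, p=P_REF), mb)
        assert cold["r_HB"] < 1e-4 and cold["theta_HB"] < 1e-3


class TestProposeChild:
    def test_zero_noise_arm_zero(self, mb):
        sp = StatePoint(T=0.2, p=P_REF)
        central = Molecule(0.0, 0.0, 0.0, shell=0)
        c = propose_child(central, 0, 0, BOND_HB, sp, mb, noise=(0.0, 0.0))
        assert (c.x, c.y) == pytest.approx((1.0, 0.0))
        assert c.theta == pytest.approx(math.pi)
        assert c.shell == 1 and c.parent == 0 and c.bond_type == BOND_HB

    def test_zero_noise_arm_one(self, mb):
        sp = StatePoint(T=0.2, p=P_REF)
        central = Molecule(0.0, 0.0, 0.0, shell=0)
        c = propose_child(central, 0, 1, BOND_HB, sp, mb, noise=(0.0, 0.0))
        assert (c.x, c.y) == pytest.approx((-0.5, math.sqrt(3) / 2))
        assert c.theta == pytest.approx(2 * math.pi / 3 + math.pi)

    def test_grandchild_lands_on_honeycomb(self, mb):
        sp = StatePoint(T=0.2, p=P_REF)
        central = Molecule(0.0, 0.0, 0.0, shell=0)
        child = propose_child(central, 0, 0, BOND_HB, sp, mb, noise=(0.0, 0.0))
        grand = propose_child(child, 1, 1, BOND_HB, sp, mb, noise=(0.0, 0.0))
        assert math.hypot(grand.x, grand.y) == pytest.approx(math.sqrt(3), abs=1e-12)

    def test_invalid_arm_for_noncentral_parent(self, mb):
        sp = StatePoint(T=0.2, p=P_REF)
        mol = Molecule(1.0, 0.0, math.pi, shell=1)
        with pytest.raises(ValueError):
            propose_child(mol, 1, 0, BOND_HB, sp, mb, noise=(0.0, 0.0))


class TestAcceptPlacement:
    def test_exact_overlap_rejected(self, mb, rng):
        sp = StatePoint(T=0.2, p=P_REF)
        existing = np.array([[0.0, 0.0], [2.0, 0.0]])
        cand = Molecule(2.0, 0.0, 0.0, shell=2)
        assert not accept_placement(cand, existing, sp, mb, rng)

    def test_soft_acceptance_at_lj_distance_is_certain(self, mb, rng):
        sp = StatePoint(T=0.2, p=P_REF)
        r_lj = mb.sigma_LJ * 2 ** (1 / 6)
        cand = Molecule(r_lj - 1e-12, 0.0, 0.0, shell=2)
        existing = np.array([[0.0, 0.0]])
        assert all(accept_placement(cand, existing, sp, mb, rng) for _ in range(20))

    def test_soft_acceptance_probability_closed_form(self, mb, rng):
        sp = StatePoint(T=0.2, p=P_REF)
        r_lj = mb.sigma_LJ * 2 ** (1 / 6)
        cand = Molecule(r_lj - 0.1, 0.0, 0.0, shell=2)
        existing = np.array([[0.0, 0.0]])
        p_expected = math.exp(-10 * 0.01 / 0.2)  # exp(-0.5)
        n = 10_000
        acc = sum(accept_placement(cand, existing, sp, mb, rng) for _ in range(n))
        assert abs(acc / n - p_expected) < 3 * math.sqrt(p_expected * (1 - p_expected) / n)


class TestGrowth:
    def test_zero_noise_all_hb_is_a_honeycomb_fragment(self, honeycomb_flake):
        r_sq = honeycomb_flake.x[1:] ** 2 + honeycomb_flake.y[1:] ** 2
        allowed = honeycomb_sq_distances()
        for v in r_sq:
            nearest = round(float(v))
            assert abs(v - nearest) < 1e-12
            assert nearest in allowed
        # the canonical shells are all present
        observed = {round(float(v)) for v in r_sq}
        assert {1, 3, 4, 7, 9} <= observed

    def test_honeycomb_nearest_neighbor_distance(self, honeycomb_flake):
        xy = np.column_stack([honeycomb_flake.x, honeycomb_flake.y])
        d = pdist(xy)
        assert d.min() == pytest.approx(1.0, abs=1e-12)

    def test_tree_property(self, ensemble_t015):
        _, ens = ensemble_t015
        for flake in ens[:200]:
            assert flake.parent[0] == -1 and flake.shell[0] == 0
            assert flake.x[0] == 0.0 and flake.y[0] == 0.0
            p = flake.parent[1:]
            assert np.all(p >= 0)
            assert np.all(flake.shell[1:] == flake.shell[p] + 1)

    def test_hardcore_audit(self, ensemble_t020, mb):
        _, ens = ensemble_t020
        for flake in ens[:100]:
            assert hardcore_violations(flake, mb) == []

    def test_shell_limit(self, ensemble_t015):
        _, ens = ensemble_t015
        assert max(int(f.shell.max()) for f in ens[:500]) <= 9

    def test_seed_determinism(self, mb):
        sp = StatePoint(T=0.25, p=P_REF)
        cfg = GrowthConfig(max_shells=5, n_replicas=3, seed=77)
        a = ensemble_list(sp, mb, cfg)
        b = ensemble_list(sp, mb, cfg)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.x, fb.x)
            np.testing.assert_array_equal(fa.y, fb.y)
            np.testing.assert_array_equal(fa.theta, fb.theta)
            np.testing.assert_array_equal(fa.bond_type, fb.bond_type)

    def test_cluster_size_grows_with_temperature(self, small_ensembles_by_T):
        mean_n = {
            T: np.mean([f.n_molecules for f in ens])
            for T, (_, ens) in small_ensembles_by_T.items()
        }
        assert mean_n[0.15] < mean_n[0.25]

    def test_first_shell_c3_symmetry(self, ensemble_t015):
        """Angular density of first-shell children is invariant under
        120-degree rotations (multinomial 3-sigma bound)."""
        _, ens = ensemble_t015
        ang = np.concatenate(
            [np.degrees(np.arctan2(f.y[1:], f.x[1:]))[f.shell[1:] == 1] for f in ens]
        )
        sector = ((ang + 60.0) % 360.0) // 120.0
        counts = np.bincount(sector.astype(int), minlength=3)
        n = counts.sum()
        for c in counts:
            assert abs(c - n / 3) < 3 * math.sqrt(n * (1 / 3) * (2 / 3))

    def test_max_shells_zero_gives_lone_center(self, mb):
        sp = StatePoint(T=0.2, p=P_REF)
        cfg = GrowthConfig(max_shells=0, n_replicas=1, seed=1)
        flake = ensemble_list(sp, mb, cfg)[0]
        assert flake.n_molecules == 1

    def test_engines_agree_on_the_deterministic_limit(self, mb, honeycomb_flake):
        sp = StatePoint(T=0.15, p=P_REF)
        cfg = GrowthConfig(
            max_shells=9, n_replicas=1, seed=123, zero_noise=True,
            populations_override=ALL_HB,
        )
        ref = ensemble_list(sp, mb, cfg, engine="reference")[0]
        key = lambda f: sorted(zip(np.round(f.x, 9), np.round(f.y, 9)))
        assert key(ref) == key(honeycomb_flake)

    def test_engines_agree_on_cluster_size_statistics(self, mb):
        sp = StatePoint(T=0.15, p=P_REF)
        cfg = GrowthConfig(max_shells=9, n_replicas=150, seed=5)
        fast = [f.n_molecules for f in ensemble_list(sp, mb, cfg, engine="fast")]
        ref = [f.n_molecules for f in ensemble_list(sp, mb, cfg, engine="reference")]
        se = math.hypot(np.std(fast, ddof=1) / math.sqrt(len(fast)),
                        np.std(ref, ddof=1) / math.sqrt(len(ref)))
        assert abs(np.mean(fast) - np.mean(ref)) < 4 * se

    def test_generator_is_lazy_and_reproducible(self, mb):
        sp = StatePoint(T=0.3, p=P_REF)
        cfg = GrowthConfig(max_shells=4, n_replicas=3, seed=9)
        it = generate_ensemble(sp, mb, cfg)
        first = next(it)
        rest = list(it)
        assert len(rest) == 2
        again = ensemble_list(sp, mb, cfg)
        np.testing.assert_array_equal(first.x, again[0].x)
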