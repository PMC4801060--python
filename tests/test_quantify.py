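"""Read-rate model (ZTNB, stacks, bootstrap) and PSI/dPSI posteriors."""

import itertools

import numpy as np
import pytest
from scipy import stats

from lsvtools.annotation_io import JunctionKey, PositionalCounts
from lsvtools.quantify import (
    BootstrapSamples,
    PriorConfig,
    bootstrap_rates,
    combine_replicates,
    dpsi_delta_factor,
    dpsi_posterior,
    dpsi_prior,
    fit_dispersion,
    flag_stacks,
    gc_correct,
    junction_rng,
    psi_posterior,
    remove_stacks,
    zero_samples,
)
from lsvtools.quantify import _beta_masses, _delta_marginalize

from conftest import junction, make_counts

UNIFORM_ONLY = PriorConfig(dpsi_mixture=((0.0, 1500, 1500), (0.0, 75, 75), (1.0, 1, 1)))


def det_samples(mu, M=1):
    return BootstrapSamples(None, M, np.full(M, float(mu)), 3)


# ---------------------------------------------------------------------------
# GC correction
# ---------------------------------------------------------------------------


def test_gc_correct_disabled_is_identity():
    pcs = [make_counts(junction(0, 10), {0: 5}, gc=0.4)]
    out = gc_correct(pcs, enabled=False)
    assert out[0].counts == {0: 5}


def test_gc_correct_equal_gc_is_identity():
    pcs = [make_counts(junction(i, i + 10), {0: 5 + i}, gc=0.5) for i in range(10)]
    out = gc_correct(pcs, enabled=True)
    for a, b in zip(pcs, out):
        assert a.counts == b.counts


def test_gc_correct_rejects_bad_gc():
    pcs = [make_counts(junction(i, i + 10), {0: 5}, gc=1.5 if i == 3 else 0.5)
           for i in range(6)]
    with pytest.raises(ValueError):
        gc_correct(pcs, enabled=True)


def test_gc_correct_shrinks_injected_slope():
    rng = np.random.default_rng(7)
    gcs = rng.uniform(0.3, 0.7, 300)
    pcs = []
    for i, gc in enumerate(gcs):
        mean = 50 * np.exp(2.0 * (gc - 0.5))  # monotone gc bias
        total = rng.poisson(mean)
        pcs.append(make_counts(junction(10 * i, 10 * i + 5), {0: total}, gc=gc))
    out = gc_correct(pcs, enabled=True)

    def slope(items):
        t = np.array([pc.total_reads for pc in items], dtype=float)
        return np.polyfit(gcs, np.log1p(t), 1)[0]

    assert abs(slope(out)) < 0.25 * abs(slope(pcs))


# ---------------------------------------------------------------------------
# ZTNB dispersion
# ---------------------------------------------------------------------------


def nb_counts(rng, n_junctions, mean, r, W=40):
    out = []
    for i in range(n_junctions):
        c = rng.negative_binomial(r, r / (r + mean), size=W)
        out.append(make_counts(junction(100 * i, 100 * i + 50),
                               {int(o): int(v) for o, v in enumerate(c) if v > 0}))
    return out


def test_dispersion_recovery_on_nb_simulation():
    rng = np.random.default_rng(11)
    pcs = nb_counts(rng, 400, mean=20.0, r=5.0)
    r_hat = fit_dispersion(pcs, seed=1)
    assert abs(r_hat - 5.0) / 5.0 < 0.25


def test_dispersion_poisson_limit_clamped():
    rng = np.random.default_rng(3)
    pcs = []
    for i in range(200):
        c = rng.poisson(20.0, size=40)
        pcs.append(make_counts(junction(100 * i, 100 * i + 50),
                               {int(o): int(v) for o, v in enumerate(c) if v > 0}))
    r_hat = fit_dispersion(pcs, seed=1)
    assert r_hat > 100.0  # far into the near-Poisson regime


def test_dispersion_deterministic_given_seed():
    rng = np.random.default_rng(5)
    pcs = nb_counts(rng, 50, 20.0, 5.0)
    assert fit_dispersion(pcs, seed=42) == fit_dispersion(pcs, seed=42)


def test_dispersion_needs_multiposition_junction():
    with pytest.raises(ValueError):
        fit_dispersion([make_counts(junction(0, 50), {0: 7})])


# ---------------------------------------------------------------------------
# stack flagging
# ---------------------------------------------------------------------------


def test_stack_flagged_against_direct_tail():
    pc = make_counts(junction(0, 50), {0: 3, 1: 4, 2: 3, 3: 5000})
    r = 5.0
    flagged = flag_stacks(pc, r, threshold=1e-7)
    assert flagged == [3]
    # oracle: direct NB upper tail with mean of the other positions
    mean_others = (3 + 4 + 3) / 3
    p = stats.nbinom.sf(5000 - 1, r, r / (r + mean_others))
    assert p <= 1e-7
    # the unflagged positions' tails are above threshold
    for off, c in [(0, 3), (1, 4), (2, 3)]:
        m = (3 + 4 + 3 + 5000 - c) / 3
        assert stats.nbinom.sf(c - 1, r, r / (r + m)) > 1e-7


def test_stack_threshold_one_flags_everything():
    pc = make_counts(junction(0, 50), {0: 3, 1: 4, 2: 3})
    assert flag_stacks(pc, 5.0, threshold=1.0) == [0, 1, 2]


def test_single_position_cannot_be_stack():
    pc = make_counts(junction(0, 50), {0: 99999})
    assert flag_stacks(pc, 5.0, threshold=1e-7) == []


def test_homogeneous_data_yields_no_flags():
    rng = np.random.default_rng(19)
    r = 20.0
    n_flags = 0
    for i in range(250):  # 250 x 40 = 10^4 positions
        c = rng.negative_binomial(r, r / (r + 20.0), size=40)
        pc = make_counts(junction(100 * i, 100 * i + 50),
                         {int(o): int(v) for o, v in enumerate(c) if v > 0})
        n_flags += len(flag_stacks(pc, r, 1e-7))
    assert n_flags <= 1


def test_remove_stacks_drops_position():
    pc = make_counts(junction(0, 50), {0: 3, 1: 5000})
    out = remove_stacks(pc, [1])
    assert out.counts == {0: 3}


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def test_bootstrap_range_and_mean_by_enumeration():
    """counts (2,2,1): brute-force enumeration of all 27 resamples gives
    E[mu] = 5; every bootstrap mu must lie in [3, 6]."""
    vals = [2.0, 2.0, 1.0]
    mus = [3 * np.mean(pick) for pick in itertools.product(vals, repeat=3)]
    assert np.isclose(np.mean(mus), 5.0)
    pc = make_counts(junction(0, 50), {0: 2, 1: 2, 2: 1})
    bs = bootstrap_rates(pc, M=3000, rng=np.random.default_rng(0))
    assert bs.W == 3
    assert bs.mu_samples.min() >= 3.0 and bs.mu_samples.max() <= 6.0
    assert abs(bs.mu_samples.mean() - 5.0) < 0.05


def test_bootstrap_single_position_has_no_variance():
    pc = make_counts(junction(0, 50), {4: 7})
    bs = bootstrap_rates(pc, M=20, rng=np.random.default_rng(0))
    assert np.all(bs.mu_samples == 7.0)


def test_bootstrap_seed_determinism():
    pc = make_counts(junction(0, 50), {0: 2, 1: 5, 2: 1})
    a = bootstrap_rates(pc, M=50, rng=junction_rng(1, "lsv1"))
    b = bootstrap_rates(pc, M=50, rng=junction_rng(1, "lsv1"))
    assert np.array_equal(a.mu_samples, b.mu_samples)
    c = bootstrap_rates(pc, M=50, rng=junction_rng(1, "lsv2"))
    assert not np.array_equal(a.mu_samples, c.mu_samples)


# ---------------------------------------------------------------------------
# PSI posterior
# ---------------------------------------------------------------------------


def test_psi_prior_only_is_jeffreys():
    post = psi_posterior("x", [zero_samples(None, 1), zero_samples(None, 1)])
    assert post.low_confidence
    np.testing.assert_allclose(post.expected_psi, [0.5, 0.5])
    expected = _beta_masses(np.array(0.5), np.array(0.5), 40)
    np.testing.assert_allclose(post.masses[0], expected, atol=1e-12)


def test_psi_closed_form_binary():
    post = psi_posterior("x", [det_samples(30), det_samples(10)])
    assert post.expected_psi[0] == pytest.approx(30.5 / 41, abs=1e-12)
    # discretized mean within one bin width of the analytic mean
    centers = (np.arange(40) + 0.5) / 40
    assert abs(post.masses[0] @ centers - 30.5 / 41) < 1 / 40


def test_psi_three_junction_prior():
    """J=3: each junction's marginal prior is Beta(1/3, 2/3)."""
    post = psi_posterior("x", [zero_samples(None, 1)] * 3)
    expected = _beta_masses(np.array(1 / 3), np.array(2 / 3), 40)
    np.testing.assert_allclose(post.masses[0], expected, atol=1e-12)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        mus=st.lists(st.floats(0.0, 200.0), min_size=2, max_size=5),
        mus_b=st.lists(st.floats(0.0, 200.0), min_size=2, max_size=5),
    )
    def test_posterior_invariants_hold_for_arbitrary_rates(mus, mus_b):
        """For any non-negative read rates: PSI masses sum to 1, E[PSI] sums
        to 1 per LSV, and dPSI masses sum to 1 with mirror antisymmetry."""
        samples = [det_samples(m) for m in mus]
        post = psi_posterior("h", samples)
        np.testing.assert_allclose(post.masses.sum(axis=1), 1.0, atol=1e-9)
        assert post.expected_psi.sum() == pytest.approx(1.0, abs=1e-6)
        J = min(len(mus), len(mus_b))
        a = dpsi_posterior("h", samples[:J], [det_samples(m) for m in mus_b[:J]])
        b = dpsi_posterior("h", [det_samples(m) for m in mus_b[:J]], samples[:J])
        np.testing.assert_allclose(a.masses.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(a.masses, b.masses[:, ::-1], atol=1e-9)
except ImportError:  # pragma: no cover - hypothesis is an optional test extra
    pass


def test_psi_normalization_invariants():
    rng = np.random.default_rng(2)
    for _ in range(20):
        J = rng.integers(2, 5)
        M = 17
        samples = [BootstrapSamples(None, M, rng.gamma(2.0, 10.0, M), 5) for _ in range(J)]
        post = psi_posterior("x", samples)
        np.testing.assert_allclose(post.masses.sum(axis=1), 1.0, atol=1e-9)
        assert post.expected_psi.sum() == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# dPSI prior and posterior
# ---------------------------------------------------------------------------


def test_dpsi_prior_uniform_reduces_to_product():
    joint = dpsi_prior(UNIFORM_ONLY)
    marg = _beta_masses(np.array(0.5), np.array(0.5), 160).reshape(40, 4).sum(axis=1)
    np.testing.assert_allclose(joint, np.outer(marg, marg), atol=1e-12)


def test_dpsi_prior_spike_concentrates_on_diagonal():
    spike = PriorConfig(dpsi_mixture=((1.0, 1500, 1500), (0.0, 75, 75), (0.0, 1, 1)))
    joint = dpsi_prior(spike)
    d = _delta_marginalize(joint, 40)
    centers = np.arange(-39, 40) / 40
    # the spike has sub-bin width: nearly all mass within one bin of zero
    assert d[np.abs(centers) <= 1 / 40 + 1e-12].sum() > 0.95


def test_dpsi_default_prior_enriches_small_changes():
    d_def = _delta_marginalize(dpsi_prior(PriorConfig()), 40)
    d_uni = _delta_marginalize(dpsi_prior(UNIFORM_ONLY), 40)
    centers = np.arange(-39, 40) / 40
    small = np.abs(centers) < 0.05
    assert d_def[small].sum() > d_uni[small].sum()


def test_dpsi_prior_bad_weights_rejected():
    with pytest.raises(ValueError):
        PriorConfig(dpsi_mixture=((0.5, 1500, 1500), (0.2, 75, 75), (0.2, 1, 1)))


def test_dpsi_uniform_prior_matches_difference_of_means():
    d = dpsi_posterior("x", [det_samples(30), det_samples(10)],
                       [det_samples(10), det_samples(30)], UNIFORM_ONLY)
    assert d.expected_dpsi[0] == pytest.approx(30.5 / 41 - 10.5 / 41, abs=2e-3)
    np.testing.assert_allclose(d.masses.sum(axis=1), 1.0, atol=1e-9)


def test_dpsi_swap_negates_posterior():
    a = dpsi_posterior("x", [det_samples(30), det_samples(10)],
                       [det_samples(12), det_samples(28)])
    b = dpsi_posterior("x", [det_samples(12), det_samples(28)],
                       [det_samples(30), det_samples(10)])
    np.testing.assert_allclose(a.masses[0], b.masses[0][::-1], atol=1e-12)
    assert a.expected_dpsi[0] == pytest.approx(-b.expected_dpsi[0], abs=1e-12)


def test_dpsi_identical_counts_centers_at_zero():
    d = dpsi_posterior("x", [det_samples(25), det_samples(25)],
                       [det_samples(25), det_samples(25)])
    assert abs(d.expected_dpsi[0]) < 1e-9
    assert d.prob_changing(0.2)[0] < 0.05


def test_dpsi_prob_changing_monotone_in_threshold():
    d = dpsi_posterior("x", [det_samples(30), det_samples(10)],
                       [det_samples(10), det_samples(30)])
    cs = [0.0, 0.1, 0.2, 0.3, 0.5]
    ps = [d.prob_changing(c)[0] for c in cs]
    assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


def test_default_prior_shrinks_toward_zero():
    """Spike-containing prior never inflates |E[dPSI]| over the uniform slab."""
    for mu_t, mu_tp in [((30, 10), (10, 30)), ((15, 5), (5, 15)), ((40, 20), (25, 35))]:
        st = [det_samples(mu_t[0]), det_samples(mu_t[1])]
        sp = [det_samples(mu_tp[0]), det_samples(mu_tp[1])]
        e_def = dpsi_posterior("x", st, sp).expected_dpsi[0]
        e_uni = dpsi_posterior("x", st, sp, UNIFORM_ONLY).expected_dpsi[0]
        assert abs(e_def) <= abs(e_uni) + 1e-12


# ---------------------------------------------------------------------------
# replicates
# ---------------------------------------------------------------------------


def test_two_identical_replicates_equal_one_doubled():
    rep = [det_samples(20), det_samples(10)]
    doubled = [det_samples(40), det_samples(20)]
    other = [[det_samples(15), det_samples(15)]]
    a = combine_replicates("x", [rep, rep], other)
    b = combine_replicates("x", [doubled], other)
    np.testing.assert_allclose(a.masses, b.masses, atol=1e-12)


def test_single_replicate_reduces_to_dpsi_posterior():
    st = [det_samples(30), det_samples(10)]
    sp = [det_samples(12), det_samples(28)]
    a = combine_replicates("x", [st], [sp])
    b = dpsi_posterior("x", st, sp)
    np.testing.assert_allclose(a.masses, b.masses, atol=1e-12)


def test_empty_replicate_contributes_nothing():
    st = [det_samples(30), det_samples(10)]
    empty = [zero_samples(None, 1), zero_samples(None, 1)]
    sp = [det_samples(12), det_samples(28)]
    a = combine_replicates("x", [st, empty], [sp])
    b = combine_replicates("x", [st], [sp])
    np.testing.assert_allclose(a.masses, b.masses, atol=1e-12)
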