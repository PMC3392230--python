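import itertools

import numpy as np
import pytest

from radsexscan.genotyper import (GENOTYPE_NAMES, GENOTYPE_PAIRS, GenotyperConfig,
                                  call_genotype, call_matrix, loglik_matrix,
                                  profile_loglik)

CFG = GenotyperConfig()


# --- independent oracle: dense grid search over the error rate --------------

def grid_loglik(genotype_idx: tuple[int, int], counts, cfg=CFG, step=1e-5):
    """Maximize the multinomial log-likelihood over eps on a dense grid."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    eps = np.arange(cfg.eps_min, cfg.eps_max + step / 2, step)
    i, j = genotype_idx
    if i == j:
        ll = counts[i] * np.log(1 - eps) + (n - counts[i]) * np.log(eps / 3)
    else:
        m = counts[i] + counts[j]
        ll = m * np.log((1 - 2 * eps / 3) / 2) + (n - m) * np.log(eps / 3)
    k = int(np.argmax(ll))
    return float(ll[k]), float(eps[k])


def enumerate_outcomes(depth):
    """All (n_A, n_C, n_G, n_T) with the given total depth."""
    for a in range(depth + 1):
        for c in range(depth - a + 1):
            for g in range(depth - a - c + 1):
                yield (a, c, g, depth - a - c - g)


def multinomial_logpmf(counts, probs):
    from scipy.special import gammaln
    counts = np.asarray(counts, float)
    return (gammaln(counts.sum() + 1) - gammaln(counts + 1).sum()
            + (counts * np.log(np.asarray(probs))).sum())


def read_probs(genotype_idx, eps):
    i, j = genotype_idx
    p = np.full(4, eps / 3)
    if i == j:
        p[i] = 1 - eps
    else:
        p[i] = p[j] = (1 - 2 * eps / 3) / 2
    return p


def call_probability(genotype_idx, eps_true, depth, cfg=CFG, want=None):
    """Exact P(call outcome) by enumeration of the multinomial read space.

    ``want`` selects the event: None = any call, "correct", "homozygous".
    """
    probs = read_probs(genotype_idx, eps_true)
    total = 0.0
    for counts in enumerate_outcomes(depth):
        counts = np.asarray(counts)
        keep = probs > 0
        if (~keep & (counts > 0)).any():
            continue
        call = call_genotype(counts, cfg)
        if not call.called:
            continue
        if want == "correct":
            i, j = genotype_idx
            if call.best_genotype != GENOTYPE_NAMES[GENOTYPE_PAIRS.index((i, j))]:
                continue
        elif want == "homozygous":
            a, b = call.best_genotype.split("/")
            if a != b:
                continue
        logp = multinomial_logpmf(counts[keep], probs[keep])
        total += np.exp(logp)
    return total


# --- profile likelihood ------------------------------------------------------

class TestProfileLoglik:
    def test_boundary_clip_pure_homozygote(self):
        lnl, eps = profile_loglik("A/A", [30, 0, 0, 0])
        assert eps == CFG.eps_min
        assert lnl == pytest.approx(30 * np.log(0.999), abs=1e-12)

    def test_interior_maximizer_homozygote(self):
        _, eps = profile_loglik("A/A", [28, 0, 2, 0])
        assert eps == pytest.approx(2 / 30, abs=1e-12)
        lnl_grid, eps_grid = grid_loglik((0, 0), [28, 0, 2, 0])
        assert profile_loglik("A/A", [28, 0, 2, 0])[0] == pytest.approx(lnl_grid, abs=1e-6)

    def test_balanced_heterozygote_clips_to_minimum(self):
        lnl, eps = profile_loglik("A/C", [10, 10, 0, 0])
        assert eps == CFG.eps_min
        assert lnl == pytest.approx(20 * np.log((1 - 2 * 0.001 / 3) / 2), abs=1e-10)
        lnl_grid, _ = grid_loglik((0, 1), [10, 10, 0, 0])
        assert lnl == pytest.approx(lnl_grid, abs=1e-6)

    def test_zero_depth_is_an_error(self):
        with pytest.raises(ValueError):
            profile_loglik("A/A", [0, 0, 0, 0])

    def test_matches_grid_oracle_on_random_counts(self):
        rng = np.random.default_rng(314)
        for _ in range(300):
            depth = int(rng.integers(1, 61))
            counts = rng.multinomial(depth, rng.dirichlet([0.5] * 4))
            lnl, _ = loglik_matrix(counts[None, :], CFG)
            for g, pair in enumerate(GENOTYPE_PAIRS):
                lnl_grid, _ = grid_loglik(pair, counts)
                assert lnl[0, g] >= lnl_grid - 1e-9
                assert lnl[0, g] - lnl_grid < 1e-6


# --- calling ------------------------------------------------------------------

class TestCallGenotype:
    def test_weak_evidence_is_no_call(self):
        call = call_genotype([3, 1, 0, 0])
        assert not call.called and call.best_genotype is None
        assert call.lnl_best == pytest.approx(-2.775, abs=1e-3)   # het A/C at eps_min
        assert call.lnl_second == pytest.approx(-3.717, abs=1e-3)  # hom A/A at eps_max
        assert call.lr_stat == pytest.approx(1.88, abs=0.01)

    def test_strong_homozygote_is_called(self):
        call = call_genotype([19, 1, 0, 0])
        assert call.called and call.best_genotype == "A/A"
        assert call.lr_stat == pytest.approx(17.6, abs=0.05)
        assert call.lr_stat >= CFG.lr_critical

    def test_zero_depth_is_no_call(self):
        assert not call_genotype([0, 0, 0, 0]).called

    def test_exact_tie_is_no_call(self):
        call = call_genotype([1, 1, 1, 1])
        assert not call.called and call.best_genotype is None

    def test_lr_invariant_under_nucleotide_relabelling(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            counts = rng.multinomial(int(rng.integers(1, 40)), rng.dirichlet([1] * 4))
            base = call_genotype(counts)
            for perm in itertools.permutations(range(4)):
                permuted = np.empty(4, dtype=int)
                permuted[list(perm)] = counts
                other = call_genotype(permuted)
                if np.isfinite(base.lr_stat):
                    assert other.lr_stat == pytest.approx(base.lr_stat, abs=1e-9)

    def test_doubling_counts_never_flips_a_call(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 1000:
            depth = int(rng.integers(5, 50))
            counts = rng.multinomial(depth, rng.dirichlet([0.8] * 4))
            call = call_genotype(counts)
            if not call.called:
                continue
            doubled = call_genotype(counts * 2)
            assert doubled.called and doubled.best_genotype == call.best_genotype
            checked += 1

    def test_call_rate_rises_with_depth_past_implicit_minimum(self):
        # Exact call probability for a true A/A at eps_true = 0.01.  The LR
        # threshold imposes an implicit minimum depth (no call is possible at
        # depth <= 4) and the rate approaches 1 at RAD-scale coverage.  The
        # rise is sawtoothed, not strictly monotone: each new error count
        # becomes callable only once depth grows enough.
        assert call_probability((0, 0), 0.01, 3) == 0.0
        p5, p10, p25 = (call_probability((0, 0), 0.01, d) for d in (5, 10, 25))
        assert 0.9 < p5 < p25 and 0.9 < p10 < p25
        assert p25 > 0.999

    def test_bounded_prior_reduces_het_to_hom_miscalls(self):
        # true heterozygote with noisy reads: compare P(called homozygous)
        bounded = GenotyperConfig(eps_min=0.001, eps_max=0.1)
        unbounded = GenotyperConfig(eps_min=0.001, eps_max=0.749)
        p_b = call_probability((0, 1), 0.05, 16, cfg=bounded, want="homozygous")
        p_u = call_probability((0, 1), 0.05, 16, cfg=unbounded, want="homozygous")
        assert p_b < p_u


# --- matrix calling -----------------------------------------------------------

class TestCallMatrix:
    def test_miscall_rate_below_one_percent_on_simulation(self, tiny_sim):
        calls, _ = call_matrix(tiny_sim.read_counts)
        gm = tiny_sim.genotypes
        truth = {}
        a1 = gm.markers["allele1"].to_numpy()
        a2 = gm.markers["allele2"].to_numpy()
        for i, marker in enumerate(gm.markers["marker_id"]):
            for k, sample in enumerate(gm.sample_ids):
                g1 = a1[i] if gm.maternal[i, k] == 0 else a2[i]
                g2 = a1[i] if gm.paternal[i, k] == 0 else a2[i]
                truth[(marker, sample)] = "/".join(sorted([g1, g2]))
        called = calls[calls["called"]]
        wrong = sum(truth[(m, s)] != g for m, s, g in
                    zip(called["marker_id"], called["sample_id"], called["genotype"]))
        assert called.shape[0] > 0.5 * len(calls)
        assert wrong / len(called) < 0.01

    def test_all_zero_depth_table_yields_no_calls(self, tiny_sim):
        table = tiny_sim.read_counts.copy()
        table[["n_A", "n_C", "n_G", "n_T"]] = 0
        calls, _ = call_matrix(table)
        assert not calls["called"].any()

    def test_summary_counts_called_individuals_per_sex(self, tiny_sim):
        calls, summary = call_matrix(tiny_sim.read_counts, sample_sheet=tiny_sim.sample_sheet)
        marker = summary["marker_id"].iloc[0]
        sub = calls[(calls["marker_id"] == marker) & calls["called"]]
        merged = sub.merge(tiny_sim.sample_sheet, on="sample_id")
        assert summary.loc[summary["marker_id"] == marker, "n_male_called"].iloc[0] \
            == (merged["sex"] == "male").sum()
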