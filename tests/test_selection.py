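"""Q-factor estimation, scoring, and rejection sampling."""

from collections import Counter

import numpy as np
import pytest

import tcrvae as tv
from tcrvae.selection import TripleKey


class SingleOutcomeProvider:
    """Provider concentrated on one triple (no exact marginals exposed)."""

    triple = tv.TcrTriple("TCRBV05-01", "TCRBJ01-01", "CASSF")

    def pgen(self, triple):
        return 1.0 if triple == self.triple else 0.0

    def sample(self, n, seed):
        return [self.triple] * n


class TableProvider:
    """Provider defined by an explicit triple->probability table, with exact
    key marginals."""

    def __init__(self, table):
        self.table = dict(table)

    def pgen(self, triple):
        return self.table.get(triple, 0.0)

    def sample(self, n, seed):
        rng = np.random.default_rng(seed)
        ts = sorted(self.table, key=lambda t: (t.v_gene, t.j_gene, t.cdr3))
        p = np.array([self.table[t] for t in ts])
        return [ts[i] for i in rng.choice(len(ts), size=n, p=p / p.sum())]

    def key_marginal(self, key):
        return sum(p for t, p in self.table.items() if tv.key_of(t) == key)

    def enumerate_keys(self):
        return sorted({tv.key_of(t) for t in self.table},
                      key=lambda k: (k.v_gene, k.j_gene, k.cdr3_length))


@pytest.fixture(scope="module")
def two_key_provider():
    return TableProvider({
        tv.TcrTriple("TCRBV05-01", "TCRBJ01-01", "CASSF"): 0.25,
        tv.TcrTriple("TCRBV05-01", "TCRBJ01-01", "CASTF"): 0.25,
        tv.TcrTriple("TCRBV30-01", "TCRBJ01-02", "CAWTF"): 0.5,
    })


class TestEstimateKeyMarginals:
    def test_exact_marginals_returned_verbatim(self, two_key_provider):
        m = tv.estimate_key_marginals(two_key_provider, n_samples=10, seed=0)
        assert m[TripleKey("TCRBV05-01", "TCRBJ01-01", 5)] == 0.5
        assert m[TripleKey("TCRBV30-01", "TCRBJ01-02", 5)] == 0.5

    def test_monte_carlo_close_to_enumeration(self, tiny_spec):
        exact = {k: tiny_spec.key_marginal(k) for k in tiny_spec.enumerate_keys()}

        class NoMarginals:  # hide the exact marginals to force Monte Carlo
            pgen = tiny_spec.pgen
            sample = tiny_spec.sample

        mc = tv.estimate_key_marginals(NoMarginals(), n_samples=100_000, seed=1)
        l1 = sum(abs(mc.get(k, 0.0) - v) for k, v in exact.items())
        assert l1 < 0.02

    def test_single_outcome_provider(self):
        m = tv.estimate_key_marginals(SingleOutcomeProvider(), 1000, seed=0)
        assert m == {TripleKey("TCRBV05-01", "TCRBJ01-01", 5): pytest.approx(1.0)}

    def test_invalid_sample_count(self, two_key_provider):
        with pytest.raises(ValueError):
            tv.estimate_key_marginals(two_key_provider, n_samples=0)


class TestFitQ:
    def test_ratio_of_empirical_to_model_probability(self, two_key_provider):
        # key (V05, J01, len 5) has model probability 0.5; make it appear
        # with empirical frequency 1.0 -> Q = 2
        t = tv.TcrTriple("TCRBV05-01", "TCRBJ01-01", "CASSF")
        qt = tv.fit_q([t] * 100, two_key_provider)
        assert qt.lookup(tv.key_of(t)) == pytest.approx(2.0)

    def test_truncation_at_q_max(self):
        table = {
            tv.TcrTriple("TCRBV05-01", "TCRBJ01-01", "CASSF"): 0.001,
            tv.TcrTriple("TCRBV30-01", "TCRBJ01-02", "CAWTF"): 0.999,
        }
        t = tv.TcrTriple("TCRBV05-01", "TCRBJ01-01", "CASSF")
        qt = tv.fit_q([t] * 100, TableProvider(table))  # ratio 1000 -> 100
        assert qt.lookup(tv.key_of(t)) == 100.0

    def test_impossible_key_warns_and_gets_q_max(self, two_key_provider):
        alien = tv.TcrTriple("TCRBV19-01", "TCRBJ01-01", "CASSF")
        with pytest.warns(UserWarning, match="impossible"):
            qt = tv.fit_q([alien], two_key_provider)
        assert qt.lookup(tv.key_of(alien)) == qt.q_max

    def test_unseen_key_uses_policy(self, two_key_provider):
        t = tv.TcrTriple("TCRBV05-01", "TCRBJ01-01", "CASSF")
        qt = tv.fit_q([t], two_key_provider, unseen_q=0.5)
        assert qt.lookup(TripleKey("TCRBV99-99", "TCRBJ01-01", 4)) == 0.5

    def test_empty_data_rejected(self, two_key_provider):
        with pytest.raises(ValueError):
            tv.fit_q([], two_key_provider)


class TestScore:
    def test_neutral_q_recovers_pgen(self, tiny_spec):
        t = tiny_spec.sample(1, seed=3)[0]
        qt = tv.QTable(q={k: 1.0 for k in tiny_spec.enumerate_keys()})
        assert tv.score(t, tiny_spec, qt) == pytest.approx(tiny_spec.pgen(t))

    def test_zero_q_kills_score(self, tiny_spec):
        t = tiny_spec.sample(1, seed=3)[0]
        qt = tv.QTable(q={tv.key_of(t): 0.0})
        assert tv.score(t, tiny_spec, qt) == 0.0

    def test_normalize_over_set_sums_to_one(self):
        out = tv.normalize_scores([0.1, 0.4, 1.2])
        assert out.sum() == pytest.approx(1.0)

    def test_normalize_rejects_all_zero(self):
        with pytest.raises(ValueError):
            tv.normalize_scores([0.0, 0.0])


class TestQTable:
    def test_values_above_q_max_rejected(self):
        with pytest.raises(ValueError):
            tv.QTable(q={TripleKey("V", "J", 5): 101.0}, q_max=100.0)

    def test_csv_roundtrip(self, tmp_path):
        qt = tv.QTable(q={TripleKey("TCRBV05-01", "TCRBJ01-01", 5): 2.5,
                          TripleKey("TCRBV30-01", "TCRBJ01-02", 7): 0.25},
                       q_max=8.0)
        path = tmp_path / "q.csv"
        qt.to_csv(path)
        loaded = tv.QTable.from_csv(path, q_max=8.0)
        assert loaded.q == qt.q


class TestRejectionSample:
    def test_q_equal_q_max_reproduces_provider_distribution(self, tiny_spec):
        qt = tv.QTable(
            q={k: 4.0 for k in tiny_spec.enumerate_keys()}, q_max=4.0)
        draws = tv.rejection_sample(tiny_spec, qt, 30_000, seed=5)
        freq = Counter(tv.key_of(t) for t in draws)
        l1 = sum(
            abs(freq.get(k, 0) / len(draws) - tiny_spec.key_marginal(k))
            for k in tiny_spec.enumerate_keys()
        )
        assert l1 < 0.03

    def test_half_acceptance_still_matches_provider(self, tiny_spec):
        # Q == q_max/2 uniformly: acceptance halves but the distribution
        # is unchanged
        qt = tv.QTable(
            q={k: 2.0 for k in tiny_spec.enumerate_keys()}, q_max=4.0)
        draws = tv.rejection_sample(tiny_spec, qt, 30_000, seed=6)
        freq = Counter(tv.key_of(t) for t in draws)
        l1 = sum(
            abs(freq.get(k, 0) / len(draws) - tiny_spec.key_marginal(k))
            for k in tiny_spec.enumerate_keys()
        )
        assert l1 < 0.03

    def test_exactly_n_and_deterministic(self, tiny_spec):
        qt = tv.QTable(q={k: 1.0 for k in tiny_spec.enumerate_keys()}, q_max=4.0)
        a = tv.rejection_sample(tiny_spec, qt, 500, seed=7)
        b = tv.rejection_sample(tiny_spec, qt, 500, seed=7)
        assert len(a) == 500 and a == b

    def test_vanishing_acceptance_raises(self, tiny_spec):
        qt = tv.QTable(q={k: 1e-6 for k in tiny_spec.enumerate_keys()},
                       q_max=100.0)
        with pytest.raises(RuntimeError, match="q_max"):
            tv.rejection_sample(tiny_spec, qt, 1000, seed=8,
                                probe_budget=20_000)

    def test_refit_on_resampled_output_is_self_consistent(self, tiny_spec):
        # fit_q . rejection_sample . fit_q idempotent up to Monte-Carlo error
        plant = tv.PlantedSelection(
            q_star={k: (2.0 if k.cdr3_length <= 6 else 0.5)
                    for k in tiny_spec.enumerate_keys()}, q_max=4.0)
        data = tv.sample_with_selection(tiny_spec, plant, 50_000, seed=9)
        qt1 = tv.fit_q(data, tiny_spec, q_max=8.0)
        redraw = tv.rejection_sample(tiny_spec, qt1, 50_000, seed=10)
        qt2 = tv.fit_q(redraw, tiny_spec, q_max=8.0)
        for k in tiny_spec.enumerate_keys():
            if tiny_spec.key_marginal(k) * 50_000 >= 500:
                assert qt2.lookup(k) == pytest.approx(qt1.lookup(k), rel=0.15)
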