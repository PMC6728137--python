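"""Model loss components, conditional likelihood, and generation."""

import numpy as np
import pytest

import tcrvae as tv
from tcrvae.encoding import SYMBOL_INDEX, encode_batch, pad_middle
from tcrvae.vae import DecoderOutput, _log_softmax, _softmax

TRIPLE = tv.TcrTriple("TCRBV05-01", "TCRBJ02-06", "CASSF")


def _uniform_output(registry) -> DecoderOutput:
    return DecoderOutput(
        v_probs=np.full(67, 1 / 67),
        j_probs=np.full(13, 1 / 13),
        cdr3_probs=np.full((30, 21), 1 / 21),
    )


def _perfect_output(x) -> DecoderOutput:
    return DecoderOutput(v_probs=x.v.copy(), j_probs=x.j.copy(),
                         cdr3_probs=x.cdr3.copy())


class TestKlDivergence:
    def test_zero_when_q_equals_prior(self):
        assert tv.kl_divergence(np.zeros(20), np.zeros(20)) == 0.0

    def test_unit_mean_one_dim_closed_form(self):
        assert tv.kl_divergence(np.array([1.0]), np.array([0.0])) == pytest.approx(0.5)

    def test_matches_monte_carlo_estimate(self, rng):
        # KL = E_q[log q - log p] estimated by sampling from q
        mu, lv = rng.normal(size=3), rng.normal(size=3) * 0.5
        closed = tv.kl_divergence(mu, lv)
        n = 100_000
        sigma = np.exp(0.5 * lv)
        z = mu + sigma * rng.standard_normal((n, 3))
        log_q = -0.5 * (((z - mu) / sigma) ** 2 + np.log(2 * np.pi) + lv).sum(1)
        log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(1)
        diffs = log_q - log_p
        se = diffs.std(ddof=1) / np.sqrt(n)
        assert abs(diffs.mean() - closed) < 3 * se

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            tv.kl_divergence(np.array([np.nan]), np.array([0.0]))


class TestGermlineMatchCounts:
    table = tv.GermlineCdr3Table({"V1": "CASS"}, {"J1": "NVLTF"})

    @pytest.mark.parametrize("cdr3,expected_v", [
        ("CASSFGG", 4), ("CGSSFGG", 1), ("GASSFGG", 0)])
    def test_v_prefix_match(self, cdr3, expected_v):
        t = tv.TcrTriple("V1", "J1", cdr3)
        assert tv.germline_match_counts(t, self.table)[0] == expected_v

    def test_j_suffix_match(self):
        t = tv.TcrTriple("V1", "J1", "CASSNVLTF")
        assert tv.germline_match_counts(t, self.table)[1] == 5


class TestReconstructionLoss:
    def test_perfect_decoder_gives_zero(self, registry):
        x = tv.one_hot_encode(TRIPLE, registry)
        cfg = tv.VaeConfig()
        assert tv.reconstruction_loss(x, _perfect_output(x), cfg) == pytest.approx(0.0)

    def test_uniform_cdr3_term_is_log21(self, registry):
        x = tv.one_hot_encode(TRIPLE, registry)
        cfg = tv.VaeConfig(loss_weights={"v": 0.0, "j": 0.0, "cdr3": 1.0})
        loss = tv.reconstruction_loss(x, _uniform_output(registry), cfg)
        assert loss == pytest.approx(np.log(21))

    def test_count_match_exact_aux_predictions_add_nothing(self, registry):
        x = tv.one_hot_encode(TRIPLE, registry)
        out = _perfect_output(x)
        out.predicted_v_match, out.predicted_j_match = 4.0, 1.0
        out.predicted_length = 5.0
        cfg = tv.VaeConfig(model_kind="count_match")
        loss = tv.reconstruction_loss(x, out, cfg, match_counts=(4, 1), length=5)
        assert loss == pytest.approx(0.0)

    def test_unnormalized_probs_rejected(self, registry):
        x = tv.one_hot_encode(TRIPLE, registry)
        out = _uniform_output(registry)
        out.v_probs = out.v_probs * 2
        with pytest.raises(ValueError):
            tv.reconstruction_loss(x, out, tv.VaeConfig())


class TestTotalLoss:
    def test_beta_zero_equals_reconstruction(self, registry):
        x = tv.one_hot_encode(TRIPLE, registry)
        out = _uniform_output(registry)
        enc = (np.ones(20), np.zeros(20))
        cfg0 = tv.VaeConfig(beta=0.0)
        assert tv.total_loss(x, enc, out, cfg0) == pytest.approx(
            tv.reconstruction_loss(x, out, cfg0))

    def test_perfect_reconstruction_and_prior_matched_encoder_is_zero(self, registry):
        x = tv.one_hot_encode(TRIPLE, registry)
        enc = (np.zeros(20), np.zeros(20))
        assert tv.total_loss(x, enc, _perfect_output(x), tv.VaeConfig()) == 0.0

    def test_monotone_in_beta(self, registry):
        x = tv.one_hot_encode(TRIPLE, registry)
        out = _uniform_output(registry)
        enc = (np.ones(20), np.zeros(20))
        losses = [
            tv.total_loss(x, enc, out, tv.VaeConfig(beta=b))
            for b in (0.0, 0.5, 1.0)
        ]
        assert losses == sorted(losses)


class TestConditionalLogProb:
    def test_probability_one_everywhere_gives_zero(self, registry):
        x = tv.one_hot_encode(TRIPLE, registry)
        assert tv.conditional_log_prob(x, _perfect_output(x)) == 0.0

    def test_uniform_closed_form(self, registry):
        x = tv.one_hot_encode(TRIPLE, registry)
        expected = np.log(1 / 67) + np.log(1 / 13) + 30 * np.log(1 / 21)
        assert tv.conditional_log_prob(x, _uniform_output(registry)) == (
            pytest.approx(expected))

    def test_zero_probability_returns_neg_inf(self, registry):
        x = tv.one_hot_encode(TRIPLE, registry)
        out = _perfect_output(x)
        out.v_probs = np.zeros(67)
        out.v_probs[0] = 1.0  # all mass off the observed V
        if x.v[0] == 1.0:
            out.v_probs = np.roll(out.v_probs, 1)
        assert tv.conditional_log_prob(x, out) == -np.inf

    def test_exponentiates_to_normalized_distribution(self, registry, rng):
        # brute-force enumeration of the (V, J, site0, site1) reduction:
        # the remaining factors each sum to one, so the reduced sum must too
        model = tv.TcrVae(tv.VaeConfig(latent_dim=2, encoder_hidden=(8, 8),
                                       decoder_hidden=(8, 8)), registry, seed=3)
        fwd = model.decode(rng.standard_normal((1, 2)))
        pv = _softmax(fwd["logit_v"])[0]
        pj = _softmax(fwd["logit_j"])[0]
        pc = _softmax(fwd["logit_cdr3"])[0]
        total = sum(
            pv[v] * pj[j] * pc[0, a] * pc[1, b]
            for v in range(67) for j in range(13)
            for a in range(21) for b in range(21)
        )
        assert total == pytest.approx(1.0, abs=1e-9)


class TestReparameterization:
    def test_draw_moments_match_encoder_parameters(self, registry):
        model = tv.TcrVae(tv.VaeConfig(latent_dim=3, encoder_hidden=(8, 8),
                                       decoder_hidden=(8, 8)), registry, seed=1)
        batch = encode_batch([TRIPLE], registry)
        mu, lv, _ = model.encode(batch)
        rng = np.random.default_rng(0)
        n = 200_000
        z = mu[0] + np.exp(0.5 * lv[0]) * rng.standard_normal((n, 3))
        np.testing.assert_allclose(z.mean(0), mu[0], atol=4 / np.sqrt(n) * np.exp(0.5 * lv[0]).max())
        np.testing.assert_allclose(z.var(0), np.exp(lv[0]), rtol=0.05)


def _concentrated_model(registry, triple) -> tv.TcrVae:
    """Decoder with essentially all probability on one triple."""
    model = tv.TcrVae(tv.VaeConfig(latent_dim=2, encoder_hidden=(8, 8),
                                   decoder_hidden=(8, 8)), registry, seed=0)
    for head in ("head_v", "head_j", "head_cdr3"):
        model.params[head + "_W"].value[...] = 0.0
        model.params[head + "_b"].value[...] = 0.0
    model.params["head_v_b"].value[registry.v_index(triple.v_gene)] = 60.0
    model.params["head_j_b"].value[registry.j_index(triple.j_gene)] = 60.0
    cdr3_b = model.params["head_cdr3_b"].value.reshape(30, 21)
    for site, sym in enumerate(pad_middle(triple.cdr3)):
        cdr3_b[site, SYMBOL_INDEX[sym]] = 60.0
    return model


class TestSampleTcr:
    def test_argmax_deterministic_given_z(self, registry):
        model = tv.TcrVae(tv.VaeConfig(latent_dim=2, encoder_hidden=(8, 8),
                                       decoder_hidden=(8, 8)), registry, seed=5)
        z = np.ones(2)
        a = tv.sample_tcr(model, z, mode="argmax", seed=1)
        b = tv.sample_tcr(model, z, mode="argmax", seed=99)
        assert a == b

    def test_generated_genes_within_registry(self, registry):
        model = tv.TcrVae(tv.VaeConfig(latent_dim=2, encoder_hidden=(8, 8),
                                       decoder_hidden=(8, 8)), registry, seed=5)
        for t in tv.generate(model, 20, seed=3):
            assert t.v_gene in registry.v_genes and t.j_gene in registry.j_genes
            assert 1 <= len(t.cdr3) <= 30

    def test_concentrated_decoder_returns_target_in_both_modes(self, registry):
        model = _concentrated_model(registry, TRIPLE)
        z = np.zeros(2)
        assert tv.sample_tcr(model, z, mode="argmax", seed=0) == TRIPLE
        assert tv.sample_tcr(model, z, mode="sample", seed=0) == TRIPLE


class TestSerialization:
    def test_roundtrip_preserves_outputs(self, registry, tmp_path):
        model = tv.TcrVae(tv.VaeConfig(latent_dim=4, encoder_hidden=(16, 16),
                                       decoder_hidden=(16, 16),
                                       model_kind="count_match"),
                          registry, seed=9)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = tv.TcrVae.load(path)
        batch = encode_batch([TRIPLE], registry)
        mu1, lv1, _ = model.encode(batch)
        mu2, lv2, _ = loaded.encode(batch)
        np.testing.assert_array_equal(mu1, mu2)
        np.testing.assert_array_equal(lv1, lv2)

    def test_metadata_mismatch_fails_loudly(self, registry, tmp_path):
        model = tv.TcrVae(tv.VaeConfig(latent_dim=4, encoder_hidden=(16, 16),
                                       decoder_hidden=(16, 16)), registry, seed=9)
        path = tmp_path / "model.npz"
        model.save(path)
        meta_path = path.with_suffix(".json")
        meta = meta_path.read_text().replace('"TCRBV05-01"', '"TCRBV05-99"')
        meta_path.write_text(meta)
        with pytest.raises(ValueError, match="metadata mismatch"):
            tv.TcrVae.load(path)
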