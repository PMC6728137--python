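# tcrvae

Generative models for T cell receptor (TCR) β-chain repertoires.

A TCR β chain is uniquely determined, at the protein level, by the triple
x = (V gene, J gene, CDR3 amino-acid sequence).  The chains observed in
blood arise from V(D)J recombination followed by thymic selection, and a
repertoire can be treated as a sample from a probability distribution over
such triples.  `tcrvae` provides two ways to fit that distribution, plus
the machinery to compare them:

- **β-VAE models** (`basic` and `count_match`): a 20-dimensional latent
  variable z with standard-normal prior, a diagonal-normal encoder
  q_φ(z|x), and a decoder p_θ(x|z) of categorical heads over V (67
  classes), J (13 classes) and 30 middle-gap-padded CDR3 sites (20 amino
  acids + gap).  Training minimises R(x, z) + β·D_KL(q_φ(z|x) ‖ p(z)) with
  a linear β warm-up, pre-training restarts and early stopping.  The
  marginal probability P_VAE(x) = E_{z∼q(z|x)}[p(x|z) p(z)/q(z|x)] is
  estimated by importance sampling through the encoder.
- **A recombination–selection baseline**: P(x) ∝ Pgen(x)·Q(V, J, |CDR3|),
  where Pgen comes from any generation-probability provider and the
  selection factors Q are maximum-likelihood ratios of empirical to
  recombination-model key frequencies (truncated at q_max), sampled from
  by rejection.

Everything is testable end to end against a built-in synthetic V(D)J
recombination simulator whose generation probabilities are exactly
enumerable, so estimators can be checked against closed-form truth without
downloading any repertoire data.  Repertoire I/O covers Adaptive
ImmunoSEQ-dialect TSV exports (parsing, the standard preprocessing filters,
cohort counting and multinomial sampling) and a canonical
`amino_acid,v_gene,j_gene,count` CSV.  Summary comparison implements 15
repertoire statistics (physicochemical CDR3 indices, length, Levenshtein
distance distributions, gene and k-mer frequencies) scored by
Jensen–Shannon or ℓ1 divergence, plus log-log cohort-frequency regression
and latent-space PCA.

## Worked example

```python
import tcrvae as tv

spec = tv.default_spec()                      # enumerable recombination model
plant = tv.default_planted_selection(spec)    # ground-truth selection factors

repertoire = tv.sample_with_selection(spec, plant, 20_000, seed=42)
qtable = tv.fit_q(repertoire, spec, q_max=8.0)

x = repertoire[0]
key = tv.key_of(x)
print(f"triple        : {x.v_gene} / {x.j_gene} / {x.cdr3}")
print(f"exact pgen    : {spec.pgen(x):.3e}")
print(f"fitted Q      : {qtable.lookup(key):.3f}  (planted {plant.lookup(key)})")
print(f"pgen * Q      : {tv.score(x, spec, qtable):.3e}")

mutant = tv.TcrTriple(x.v_gene, x.j_gene, x.cdr3[:-2] + "Q" + x.cdr3[-1])
print(f"mutant {mutant.cdr3}: pgen = {spec.pgen(mutant)}")
```

prints

```
triple        : TCRBV30-01 / TCRBJ01-02 / CANYGYTF
exact pgen    : 6.000e-03
fitted Q      : 0.833  (planted 1.0)
pgen * Q      : 5.000e-03
mutant CANYGYQF: pgen = 0.0
```

The triple drawn is a CAW-prefix V segment trimmed by one residue joined
directly onto the NYGYTF suffix of TRBJ1-2; its generation probability is
exactly enumerable (6·10⁻³).  The fitted selection factor estimates the
planted factor divided by the selected distribution's normalising constant
(here ≈1.2, so a neutral key fits at ≈0.83); multiplying gives the
unnormalised repertoire score.  The point mutation inside the
germline-encoded suffix (T→Q two positions from the end) cannot be produced
by any trim/insertion scenario, so its generation probability is exactly
zero — the hallmark of recombination models that VAE models must learn
from data.

Training a VAE and estimating sequence probabilities follows the same
pattern (about 90 s on one CPU for 5,000 sequences):

```python
model, report = tv.train(repertoire[:5000], "basic", tv.TrainConfig(seed=7))
est = tv.log_pvae(x, model, n_samples=100, seed=0)
print(est.log_probability, est.standard_error_log)
```

The same pipeline is available from the shell via `tcrvae simulate`,
`tcrvae train`, `tcrvae pvae`, `tcrvae generate`, `tcrvae fit-q`,
`tcrvae sample-q`, `tcrvae evaluate`, `tcrvae latent` and
`tcrvae preprocess` (ImmunoSEQ TSV → filtered canonical CSV); every
subcommand takes a flat JSON `--config` overridable by flags and writes a
`.run.json` sidecar with the effective configuration and package version.

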