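# Methods

## Problem and model

`idrfuse` tags each residue of a protein sequence as **ordered** or
**disordered** (intrinsically disordered regions, IDRs — segments without a
stable 3D structure). Two per-residue feature streams are used:

* a **traditional biological block** `R^b ∈ R^{L×80}` — PSI-BLAST PSSM
  log-odds (20 columns, logistic-squashed by default), a 20-component PCA of
  AAindex physicochemical scales (566 indices over the 20 amino acids), and
  two 20×20 pairwise contact-potential tables contributing the residue's row
  from each (40 columns);
* a **protein-language-model block** `R^p ∈ R^{L×D_p}` — the ordered
  concatenation of per-residue embeddings from pluggable backends. The
  canonical registry is ProtT5 (1024), ESM-2 (1280), DR-BERT (768),
  OntoProtein (30), giving `D_p = 3102`. Real weights are out of scope:
  backends implement `name / dim / embed`, and deterministic mock backends at
  the same widths are the test path.

The network has three stages.

**Multi-semantic interaction layer.** A gated recurrent cell processes the
sequence left to right. At residue *j* the traditional features modulate the
previous memory cell,

```
C^b   = σ(W_c C_{j−1} + b_c) ⊙ σ(W_r R^b_j + b_r)
```

while the PLM features drive the three gates and the candidate memory exactly
as in an LSTM:

```
[f, i, o] = σ(W_g [R^p_j ; h_{j−1}] + b_g)
Ĉ         = tanh(W_ĉ [R^p_j ; h_{j−1}] + b_ĉ)
C_j       = f ⊙ C^b + i ⊙ Ĉ
h_j       = o ⊙ tanh(C_j)
```

The two streams therefore interact **multiplicatively** inside the cell
rather than being concatenated. The per-position hidden states
`h_1 … h_L` form the layer's output. A `concat_lstm` mode replaces the cell
with a textbook LSTM over `[R^b_j ; R^p_j]` — the ablation baseline, verified
against an independent plain-numpy LSTM to 1e-6.

Two readings of "where the fused memory enters the standard update" are
dimensionally possible; we consume `C^b` in place of `C_{j−1}` inside the
forget path (`C_j = f ⊙ C^b + i ⊙ Ĉ`), the only reading in which the fused
memory is actually used. An additive variant
(`C_j = f ⊙ C_{j−1} + i ⊙ Ĉ + C^b`) is exposed behind
`ModelConfig.additive_memory` for experimentation and is off by default.

**Transformer encoder.** `N` post-norm sublayers of masked multi-head scaled
dot-product attention (`softmax(QKᵀ/√d_k)V`, key positions beyond the valid
prefix receive −1e9 before the softmax) and a position-wise ReLU feed-forward
network (`max(0, xW₁+b₁)W₂+b₂`), each wrapped in residual + layer-norm. A
learned input projection maps the recurrent output width to `d_model` when
they differ.

**Output head.** A linear map to two logits and a softmax; the reported score
is the disordered-class probability, binarized at threshold 0.5
(score ≥ 0.5 → disordered).

## Masking

Three masks are enforced everywhere and tested metamorphically:

* **padding** must be a trailing suffix; the recurrent layer zeroes padded
  outputs, attention gives padded keys zero weight, and a padded forward pass
  reproduces the unpadded one at valid positions to 1e-5;
* **unlabeled residues** (state `-`, e.g. residues absent from X-ray data in
  CAID-style annotations) contribute exactly zero to the loss, the confusion
  counts, AUC, APS and Fmax;
* `pad_or_truncate` provides the fixed-length comparison mode (default 500):
  longer proteins keep their first `max_len` residues, shorter ones are
  zero-padded with a validity mask.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `d_h` | 64 | recurrent hidden width |
| `d_model` | 64 | encoder width (input-projected from `d_h` or `2 d_h`) |
| `n_layers` | 2 | encoder sublayers |
| `n_heads` | 4 | attention heads (`d_k = d_model / n_heads`) |
| `d_ff` | `2·d_model` | feed-forward inner width |
| `dropout` | 0.1 | after attention and FFN, training only |
| `bidirectional` | off | optional reverse pass with independent weights |
| `positional_encoding` | off | sinusoidal; the recurrence already injects order |
| `threshold` | 0.5 | binarization threshold on the disorder score |
| `epochs / batch / lr` | 20 / 32 / 3e-3 | Adam, seeded shuffling |

These architecture and optimizer values are the package's own documented
stand-ins — small enough to train on one CPU in minutes while exercising
every component. Initialization is fan-in-scaled uniform; the forget-gate
bias starts at +1 (standard LSTM practice); gate stacking order is fixed as
[forget, input, output]; all randomness flows from one integer seed.
Training retains the parameters with the best validation AUC; optional
inverse-frequency class weighting is off by default.

## Feature-encoding choices

* **PSSM**: the first (log-odds) 20-column block of the PSI-BLAST ASCII
  profile; logistic scaling `x → 1/(1+e^{−x})` on by default, raw integers
  available (`scaling=False`).
* **AAindex**: per-index mean imputation over the 20 amino acids, per-index
  z-scoring (scale floored at 1e-12 so constant indices contribute ~0), then
  the top-20 principal directions of the 20 row-profiles; component signs are
  fixed by forcing each component's largest-magnitude loading positive. The
  encoding is a per-letter lookup, so it is dataset-independent. `X`
  (nonstandard residue) takes the mean profile, which projects to zero.
* **Energy**: per residue, its row from each of the two symmetric 20×20
  contact-potential tables; `X` takes each table's column mean.
* The packaged AAindex profiles and contact-potential tables are **synthetic
  stand-ins**, generated deterministically and labelled as such
  (`synthetic_aaindex_profiles`, `contact_potential_synthetic_{a,b}.tsv`);
  loaders accept user-supplied real tables in the same formats.

## Synthetic data generator

`simulate_dataset` emulates the *structure* of the task, not its biology.
Per residue: a two-state Markov chain proposes segmental order/disorder
(`p_enter = 0.05`, `p_exit = 0.10`, mean segment lengths 20 and 10); two
latent AR(1) signals `u, v` with smoothing `rho = 0.8` and standard-normal
innovations (marginal s.d. ≈ 1.67); disorder probability

```
π_j = logistic(β_b u_j + β_p v_j + β u_j v_j + γ·1[s_j = disordered])
```

with defaults `β = 3, β_b = β_p = 0.5, γ = 1`; label ~ Bernoulli(π).
Stream `R^b` carries `u` in its first 8 of 80 columns plus N(0, 0.5²) noise,
stream `R^p` carries `v` in its first 8 of 64 columns likewise; all other
columns are pure noise. A fraction 0.1 of residues is relabeled unlabeled.
The default PLM width (64, not 3102) is a deliberate study-scale choice so
the experiments below train in minutes on one CPU.

Because the label depends on the **product** `u·v`, with `β_b = β_p = 0`
either stream alone is provably uninformative (single-stream Bayes AUC ≈ 0.5)
while both together separate well (AUC > 0.9) — the construction that makes
feature fusion necessary rather than convenient. The latents are retained on
the dataset object so `bayes_scores` can return the true `π_j`: the ceiling
for any model. They are never written to the feature files a model reads.

What the generator does **not** emulate: realistic amino-acid composition,
evolutionary covariance between PSSM columns, or the geometry of real PLM
embeddings. Passing the experiments below therefore demonstrates that the
architecture can exploit multiplicative cross-stream structure and that the
pipeline is correct end to end — not that it reaches any particular accuracy
on real proteins.

## The fusion-vs-concatenation experiment

The package's headline comparison trains both fusion modes under paired
seeds on the default synthetic dataset (200 proteins, lengths 50–150), with
the study-scale model `d_h = 32, d_model = 32, N = 1, k = 4`, 20 epochs,
five seeds, 5-fold protein-level splits (fold 0 held out). Reported per
seed: best validation AUC of each mode and the Bayes-oracle AUC on the same
validation residues. The expected picture — reproduced by
`scripts/acceptance.py` and the test suite — is fusion ≥ concatenation in at
least 4 of 5 seeds, fusion mean AUC well above 0.85, and both below the
oracle (≈ 0.95). Problem sizes were chosen as the package's study
configuration; larger models and datasets only widen the compute, not the
logic.

## Numerical choices and degenerate inputs

* Compute core: a small reverse-mode autodiff engine on numpy float64
  (`idrfuse._autodiff`), gradient-checked against central finite differences
  through the full bidirectional network.
* Attention logits are max-subtracted before the softmax; masked keys get
  −1e9. A query whose keys are all masked is an error.
* Zero-denominator threshold metrics are reported as 0 and named in
  `MetricsReport.degenerate`. AUC requires both classes; APS/Fmax require a
  positive — violations raise rather than returning a silent value.
* Evaluation pools residues dataset-wide (each labeled residue weighted
  equally); per-protein averaging is available behind a flag.
* PCA asks for at most `min(n_samples, n_features)` components; the 20th
  component of column-centered 20-row data has ~0 variance but remains an
  orthonormal direction.
* Ties in ranking metrics count one half (Mann–Whitney convention); APS is
  the step-wise recall-weighted precision sum.

## Known limitations

* Mock PLM backends share no geometry with real embeddings; plugging in real
  backends (same interface) is supported but untested against the published
  models.
* The packaged AAindex/contact-potential tables are synthetic; results on
  real proteins require the user to supply real tables and PSSM profiles.
* Training is CPU-bound pure numpy; it is sized for method study, not for
  corpus-scale fitting.
* Bootstrap confidence intervals on the metric suite are not implemented.
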