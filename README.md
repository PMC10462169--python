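# sgnc — stochastic generative network complex

Latent-space generation of multi-target lead candidates: a multi-reference
Langevin sampler over a molecular latent space, coupled to per-target
binding-affinity regressors and a multi-criteria drug-likeness screening
cascade. Built for computational chemists prototyping multi-target lead
generation — the default target panel is the cocaine-addiction one
(dopamine, norepinephrine and serotonin transporters as therapeutic
targets, the hERG potassium channel as the cardiotoxicity anti-target),
but every stage is target-agnostic.

## The model

Molecules live in the latent space of an encoder/decoder (the *codec*; a
pluggable contract, with a deterministic nearest-neighbor codebook codec
built in for desk-scale work). Given reference compounds with latent
vectors X_k and weights a_k (Σ a_k = 1), a seed vector X(0) evolves by the
Langevin equation

    dX/dt = α Σ_k a_k (X_k − X) + ξ(t)

— mean reversion toward the weighted reference centroid m = Σ a_k X_k plus
small bounded noise ξ (uniform in [−0.1, 0.1] per coordinate by default;
Gaussian and clipped-Gaussian laws are also available). With Gaussian
noise this is an Ornstein–Uhlenbeck process with stationary law
N(m, σ²/(2α)·I), which the test suite uses as an analytic oracle for the
Euler–Maruyama discretization.

Trajectory snapshots are decoded to SMILES, deduplicated, and pushed
through the cascade:

1. **Affinity filter** — predicted ΔG < −9.54 kcal/mol on each transporter
   (Ki below 0.1 μM) and ΔG > −8.18 kcal/mol on hERG (Ki above 1 μM), via
   per-target MLP regressors (512/1024/512 hidden units, Adam, batch 16,
   two-phase learning rate) on latent features.
2. **Novelty filter** — cosine similarity to every reference < 0.5.
3. **Lipinski's rule of five** — MW ≤ 500, logP ≤ 5, nHD ≤ 5, nHA ≤ 10.
4. **Property screening** — ten ADMET/physicochemical/medicinal-chemistry
   properties classified excellent/medium/fail against a built-in range
   table (values are consumed from a CSV, e.g. an ADMET predictor export;
   never predicted here).

Survivors are ranked by the percentage of properties in the excellent
range. Reference compounds themselves are selected per target by strict
criteria: ΔG < −9.54 kcal/mol, Lipinski pass, and average cosine
similarity to the target's dataset > 0.40. See `docs/methods.md` for the
full model description, boundary conventions and limitations.

## Worked example

A complete run on the built-in synthetic study conditions (50 molecules
per target plus a cross-screened multi-target family, 16-dimensional
latent space, planted linear affinity maps):

```bash
sgnc run --seed 7 --out demo/
```

prints the stage counts to standard error and writes `demo/leads.csv` and
`demo/report.json`:

```
{"decoded": 201, "deduplicated": 21, "affinity_pass": 8, "novelty_pass": 2,
 "lipinski_pass": 2, "screening_pass": 1}
```

201 trajectory snapshots decode to 21 unique molecules; 8 satisfy the
four-target affinity requirement; 2 of those are dissimilar (cosine < 0.5)
from all three references; both pass Lipinski; 1 survives the ten-property
screen and is ranked. The lead row records its predicted panel — e.g.
ΔG(DAT) = −10.68, ΔG(NET) = −9.88, ΔG(SERT) = −10.10 kcal/mol (all below
the −9.54 activity cut-off) and ΔG(hERG) = −6.25 (safely above −8.18) —
plus its per-property classes and a percent-excellent score of 100. The
report also carries the latent-profile divergence diagnostic (0.33 here):
surviving candidates are re-encoded and their per-index |mean| profile
compared against the training set's, the feedback-loop check that the
generator stayed inside the encoder's distribution.

The same cascade runs from your own files
(`--config run.yaml` pointing at dataset/latent/property CSVs), and each
stage is available separately: `sgnc make-fixtures`, `sgnc select-refs`,
`sgnc train-predictors`, `sgnc generate`, `sgnc screen`.

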