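# Methods

## The generative model

Molecules are represented as points in the latent space of a
sequence-to-sequence autoencoder (dimension d, 512 in full-scale use). Given
K reference compounds with latent vectors X_k and positive weights a_k with
Σ a_k = 1, the generator evolves a latent state X by the Langevin equation

    dX/dt = α · Σ_k a_k (X_k − X) + ξ(t),

a mean-reverting drift toward the weighted reference centroid m = Σ a_k X_k
plus a small random forcing ξ. With Gaussian ξ this is an
Ornstein–Uhlenbeck process: the zero-noise solution is
X(t) = m + (X(0) − m)·e^(−αt), and the stationary law is N(m, σ²/(2α)·I).
Both closed forms are used as analytic oracles in the test suite, never in
the sampler itself.

Integration is explicit Euler–Maruyama,

    x' = x + Δt·α·Σ_k a_k (X_k − x) + η,

which contracts toward m with factor |1 − αΔt| per step; αΔt < 1 is
enforced at configuration time. α = 0 is allowed and switches the drift off.

**Noise laws.** Three per-coordinate laws are exposed:

* `gaussian` — η ~ N(0, (A√Δt)²): the mathematically clean choice; all
  stationary-moment tests use it because its limit law is known exactly.
* `uniform` (default, A = 0.1) — η ~ U[−A, A]: bounded editing of the
  latent vector. Bounded noise is what keeps edited vectors inside the thin
  region of latent space a real decoder can map back to valid structures,
  so it is the operational default.
* `clipped-gaussian` — the Gaussian draw clipped to [−A, A].

An optional Euclidean cap on the per-step displacement is available as a
further guard (off by default). Because the uniform amplitude is fixed per
step (not √Δt-scaled), its stationary spread grows as A/√(2αΔt): the
integration step doubles as an exploration radius control, and the pipeline
default (Δt = 0.005) is chosen so the stationary cloud spans several
codebook cells at the synthetic fixture's geometry.

**Candidate emission.** Snapshots are taken every `snapshot_every` steps
after `burn_in`, decoded to SMILES, and deduplicated keeping first
occurrence. The pipeline default takes snapshots from step 0 so the
approach path contributes candidates as well as the stationary cloud.

## Codec contract and the codebook stand-in

Production encoders/decoders plug in through a two-method contract
(`encode`, `decode`, plus a `dimension`). The built-in `CodebookCodec` is a
deliberately simple, fully deterministic stand-in for desk-scale work: each
known molecule owns one latent center; encoding is exact lookup; decoding
maps any vector to the SMILES of the nearest center in Euclidean distance
(ties to the lowest index). Its reconstruction rate on its own codebook is
exactly 1 by construction, which the validation operation checks.
Reconstruction comparisons canonicalize SMILES through rdkit when it is
importable and fall back to raw string equality otherwise.

The per-index latent profile (|mean| over a set of vectors per coordinate;
the mean-of-absolute variant is also available) and its mean-absolute-
difference divergence implement the distribution-shift diagnostic: after a
run, surviving candidates are re-encoded and their profile compared with
the training set's.

## Affinity regressors

One regressor per protein target (DAT, NET, SERT, hERG) maps a latent
vector to a binding free energy ΔG in kcal/mol. The network is a
fully-connected MLP with three hidden layers (512/1024/512 rectifier units
by default), Adam, batch size 16, minimizing mean squared error under a
two-phase learning-rate schedule: 1e-4 for the first half of the epochs,
1e-5 for the rest (1000 total by default). The implementation rides on
scikit-learn's `MLPRegressor`; the phase change is realized by a
warm-started second fit and in-training early stopping is disabled so the
schedule runs literally. The estimator is scikit-learn compatible
(`fit`/`predict`, `get_params`/`set_params`, `model_` fitted attribute) and
deterministic given its `random_state`.

Model quality is reported as k-fold (default 10) cross-validated Pearson R
and RMSE. Rows are shuffled once from the seed, folds are near-equal and
partition the sample; both pooled (over concatenated out-of-fold
predictions) and fold-averaged metrics are reported, since either
convention appears in practice.

Desk-scale configurations (smaller hidden layers, tens of epochs, a hotter
first-phase learning rate) are used throughout the tests and the pipeline
default so a full run completes in seconds; the recovery tests in the
acceptance suite use the full architecture with 30 epochs (20 at 1e-4,
10 at 1e-5), which on planted linear signal reaches pooled R ≈ 0.97
noiseless and ≈ 0.96 at 0.5 kcal/mol label noise.

## Unit conversions

ΔG = −RT·ln Ki is evaluated through the composite factor
ΔG ≈ 1.3633 × log10(Ki[M]) kcal/mol conventionally printed at
R = 1.987 cal/mol·K, T = 298.15 K. The composite factor is used verbatim
rather than recomputed from the constants (which would give ≈ 1.3641),
because it is the factor that reproduces the two standard cut-offs exactly:
Ki = 0.1 μM ↔ −9.54 kcal/mol (tight binder) and Ki = 1 μM ↔ −8.18 kcal/mol
(the hERG safety margin), both after rounding to two decimals. IC50
converts to Ki by the flat competitive/uncompetitive approximation
Ki = IC50/2, with no inhibition-mode switch. Dataset readers accept Ki with
unit tags (M, mM, uM, nM, pM) and normalize to ΔG on read.

## Reference selection

References for the generator are chosen per transporter target among
records labelled for that target, by three joint criteria (all strict
inequalities, following the "less than / greater than" convention):
ΔG < −9.54 kcal/mol, Lipinski's rule of five, and average cosine similarity
to the target's dataset > 0.40. The average excludes the candidate's own
self-comparison (including it would inflate every average by ~1/n).
Survivors are ranked by average similarity descending, ties by more
negative ΔG, then by id, making the ranking total and deterministic.
Similarity operates on latent vectors only; fingerprint similarity is out
of scope.

## Screening cascade

* Affinity filter: ΔG < −9.54 kcal/mol on DAT, NET and SERT, and
  ΔG > −8.18 kcal/mol on hERG, all strict.
* Lipinski: MW ≤ 500 Da, logP ≤ 5, nHD ≤ 5, nHA ≤ 10 — inclusive
  boundaries.
* Novelty: cosine similarity to every reference < 0.5.
* Property ranges (ten properties; values are consumed from a table, never
  predicted — mirroring their origin in an external ADMET predictor):
  Caco-2 permeability > −5.15 (strict, no medium band); F20%,
  P-gp substrate, P-gp inhibitor, T1/2 and FDAMDD scores excellent in
  0–0.3 with a medium band to 0.7; VD excellent in 0.04–20 L/kg; SAS < 6
  (strict); logP in 0–3 and logS in −4–0.5 log mol/L.

Boundary conventions where the printed ranges touch: two-sided excellent
intervals are closed, medium bands are half-open excluding the shared
excellent boundary (0.3 classifies excellent), one-sided ranges are strict
as printed, and properties without a medium band fail outright outside
excellent. The five score-type properties are validated to [0, 1]. Overall
pass requires at least medium on all ten properties; the ranking score is
the percentage of properties in the excellent range, ties broken by id.
The filters commute: the survivor set is independent of application order
(property-tested).

## Synthetic study conditions

The fixture generator fabricates the three inputs a real deployment
downloads or computes, with the statistical structure the pipeline assumes:

* **Latent clusters.** One center per target drawn at norm 3 with cluster
  spread 0.6 in d = 16 (512 is the full-scale default; 16 keeps the suite
  fast). These values put within-family cosine similarity around 0.6 —
  comfortably above the 0.40 selection criterion — while keeping families
  angularly separate.
* **Planted affinities.** Global linear maps ΔG = w_t·z + b_t per target
  (weight scale 0.3), intercepts set so the noiseless label at each
  cluster center is −11 kcal/mol for transporters (tight) and −7 for hERG
  (weak); label noise SD 0.5 kcal/mol. The maps are emitted as ground
  truth so recovery tests assert against them rather than re-deriving.
* **A multi-target bridge family** (`multi_target_fraction`, default 0.2
  per transporter): extra molecules drawn around the mean of the three
  transporter centers and labelled on all four targets through the planted
  maps — the synthetic analogue of cross-screened triple-reuptake-inhibitor
  chemistry counter-screened on hERG. This family is what makes the
  multi-target affinity filter satisfiable at all in the codebook world,
  and it is exactly the region the drift samples; without it every run
  would end at zero by construction.
* **Descriptors and properties.** Lipinski descriptors are sampled inside
  declared ranges (MW 250–520, logP 0.5–5.5, nHD 0–6, nHA 1–11), not
  computed from structure, so most but not all molecules pass. Property
  profiles are drawn class-first: each property's class comes from planted
  probabilities (default 0.6/0.3/0.1 excellent/medium/fail; the medium mass
  folds into excellent for properties with no medium band), then a value is
  sampled strictly inside that class's interval. Planted classes equal the
  classifier's output by construction, which is asserted.
* **Synthetic SMILES** come from a tiny valid-by-construction grammar (a
  structural prefix plus an alkyl chain whose length encodes the index):
  unique, rdkit-parseable, stable under canonicalization.

What the fixtures do **not** emulate: real activity distributions, real
chemistry (descriptors are independent of structure), a decoder that can
emit molecules outside its training set, or correlated ADMET properties.
Passing tests therefore demonstrate the correctness of the machinery —
discretization, filters, rankings, determinism — not chemical validity of
generated leads on real data.

## Seeds and determinism

Every stochastic component takes an explicit seed; the pipeline derives
per-stage seeds from one root seed by fixed offsets, so stages can be
re-run in isolation and two identical configs produce byte-identical lead
CSVs and reports (asserted in the acceptance suite). Nearest-neighbor ties
in decoding break to the lowest codebook index; ranking ties break by id.

## Problem sizes used by the test suite

Unit and property tests run at d = 4–16 with tens to hundreds of
molecules. The OU stationary-moment check uses α = 1, σ = 0.2, Δt = 0.01,
2×10⁵ steps after 10⁴ burn-in in d = 4, testing the mean within 4 standard
errors (with an effective sample size discounting the ~1/(αΔt)-step
autocorrelation) and the variance within 10%. Cross-validation recovery
uses n = 500, d = 16 (n = 200 for the pure-noise null) with the full
512/1024/512 architecture at 30 epochs. The end-to-end runs use 30
molecules per target and 1200–2000 generator steps.

## Known limitations

* The codebook codec can only ever return catalogued molecules; novelty in
  the chemical sense requires plugging in a real autoencoder through the
  codec contract.
* The uniform noise law has no exact stationary closed form; quantitative
  moment validation is done under the Gaussian law only.
* IC50→Ki uses the flat factor 2 regardless of inhibition mode, and the
  Ki↔ΔG factor is the printed composite, not RT·ln10 recomputed.
* The screening thresholds are fixed convention; no calibration against
  measured ADMET outcomes is attempted.
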