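# Methods

## Problem and scope

`qsarkit` builds quantitative structure–activity relationship (QSAR)
regression models that predict the potency (pIC50) of small-molecule kinase
inhibitors from molecular descriptors, optionally fused with per-compound
docking-energy terms. It targets the wild-type / mutant EGFR setting: two
inhibitor chemotypes (quinazolines against the wild-type kinase;
imidazothiazole/pyrazolopyrimidine-like scaffolds against the L858R mutant),
three modelling protocols (wild, mutant, and a hybrid pooling both classes),
and the cross-class question — how badly does a model trained on one
chemotype predict the other?

Potency is expressed as pIC50 = −log10(IC50 [M]) = 9 − log10(IC50 [nM]),
the standard molar convention; a raw-nM variant (−log10 of the nM value) is
available behind a flag for compatibility with sources that log the nM
number directly.

## Descriptors

A single open engine (RDKit) computes six descriptor families:

| family | type | count | contents |
|---|---|---|---|
| `physicochemical` | continuous | 11 | MolWt, logP, MR, TPSA, HBD/HBA, rotatable bonds, Fsp3, ASA, partial-charge extrema |
| `topological` | continuous | 11 | Balaban J, Bertz CT, χ and κ indices, Hall–Kier α |
| `constitutional` | continuous | 13 | heavy atoms, ring counts, N/O/S/halogen counts |
| `substructure_fp` | binary | 36 | curated SMARTS keys (amines, ethers, carbonyls, halogens, azine/azole cores, ...) |
| `path_fp` | binary | 256 | hashed path-based fingerprint |
| `maccs_like_fp` | binary | 166 | MACCS structural keys |

Descriptor names do not map one-to-one onto any commercial engine's names;
constant columns are retained at this stage (removal is the selection
pipeline's job). Docking energies are never computed here — they are
ingested from CSV as seven named columns (`E_FreeBind`, `E_InterMol`,
`E_VHD`, `E_Elec`, `E_FToT`, `E_Tors`, `E_Unb`, kcal/mol) and may be
pre-screened by pairwise Pearson correlation: from each pair above the
cutoff (default 0.9) the member with the larger mean absolute correlation to
the remaining terms is dropped, which deterministically reproduces the
choice of discarding the intermolecular energy when it tracks the
vdW+Hbond+desolvation term.

## Feature selection

Four stages, in order, each a pure function of (matrix, activity, config,
seed) with lexicographic tie-breaks:

1. **Degenerate removal** — all-zero and zero-variance columns.
2. **Correlation pruning** (cutoff 0.9) — the worst offending pair is
   resolved first; the member with the smaller |correlation to activity| is
   removed; the survivor set provably contains no pair above the cutoff.
3. **CFS subset search** — subsets scored by the correlation-based merit
   k·r̄_cf / √(k + k(k−1)·r̄_ff). Exhaustive enumeration up to 15 features,
   otherwise best-first forward search (10,000-expansion budget, stop after
   5 stale expansions). The classical implementation's *locally predictive*
   post-pass is on by default: left-out features are admitted, most
   activity-correlated first, whenever their activity correlation exceeds
   their correlation with every already-selected feature. This rescues
   independently informative features that the redundancy denominator of
   the merit alone would discard.
4. **Remove-one backward elimination** — each cycle scores every
   leave-one-descriptor-out subset by the 5-fold cross-validated Pearson R
   of the SVR (folds fixed by seed and shared across subsets) and
   permanently removes the descriptor whose removal yields the largest R
   that is at least the current R; the loop stops when every removal would
   decrease R, so the R trajectory is non-decreasing by construction.
   Training-set R is deliberately not used — it would make removal scoring
   trivially monotone.

A feature budget of floor(n_compounds / 4) guards against
over-parameterisation; when it binds, features are ranked by |correlation
to activity|.

Within `run_protocol`, selection runs once on the whole scoped dataset and
the resulting descriptor set is reused by the whole-set, cross-validated
train, and held-out validation evaluations — the classical QSAR protocol.
The consequence is worth stating plainly: the validation metrics assess the
model under that protocol, not a selection-blind generalisation estimate.
`select_features` can of course be applied to any subset when a fully
nested estimate is wanted.

## Regression model

Epsilon-SVR on standardised features (per-column mean/SD stored in the
model bundle). Defaults: RBF kernel, C = 10, ε = 0.1, γ = 1/n_features —
chosen as sensible mid-range values since the original hyperparameters are
not recorded anywhere. Linear and polynomial kernels are available.
Prediction is an explicit kernel evaluation over the stored support vectors
and dual coefficients, so a saved model (a single JSON file, no pickles)
reproduces predictions bit-for-bit; parity of this evaluation with the
fitting engine is asserted in the tests to 1e-10.

Cross-validation pools out-of-fold predictions over a seeded k-fold
partition (default 5) and reports the four statistics on the pooled vector.

## Evaluation statistics

* R — Pearson product-moment correlation between observed and predicted.
* R² — coefficient of determination 1 − SSE/SST, SSE = Σ(obs − pred)²,
  SST = Σ(obs − mean(obs))². This measures agreement with the identity
  line; it is not in general the square of R and can be negative for a
  biased predictor.
* MAE, RMSE — mean absolute and root-mean-squared residual; RMSE ≥ MAE
  always.

Degenerate inputs fail loudly: correlations are errors (not NaN) on
constant vectors, R² is an error when SST = 0.

## Fragment enrichment

A "fragment" is a binary fingerprint bit; presence is per-molecule
(multiple occurrences within one molecule count once). For fragment f and
class c the enrichment ratio is

    frequency(f, c) = (N_fc / N_c) / (N_f / N)

— class prevalence over overall prevalence. It satisfies the conservation
identity Σ_c (N_c/N)·frequency(f, c) = 1 for every fragment that occurs at
all, equals 1 under no enrichment, and attains N/N_c for a class-exclusive
fragment. Strict class-exclusive detection (present in every molecule of
one class, absent from the other) is complemented by a relaxed variant with
prevalence thresholds (default 0.9 inside / 0.1 outside), and
common-fragment listing takes a minimum prevalence both classes must reach.

## Synthetic data generator

Real curated inhibitor series are not redistributable, so the generator
emulates their statistical shape:

* **Chemistry** — a 4-anilinoquinazoline template varied at four positions
  (fused ring, C2, two aniline positions) for the wild class and a
  4-amino-pyrazolo[3,4-d]pyrimidine varied at three for the mutant class,
  with substituent alphabets of 22 (aromatic-carbon) and 9 (pyrazole-N)
  med-chem groups. Ring closures inside substituents use digit 9 to avoid
  colliding with template ring numbering during splicing. Variants are
  drawn uniformly without replacement under the seed.
* **Activity** — pIC50 = 7.0 + Σ w_j·bit_j + class offset + N(0, σ), with
  σ = 0.3 log units by default and an optional interaction term for
  nonlinear tests. The planted bits are auto-picked to be *identifiable*:
  prevalence 0.2–0.8, no other column correlated above 0.8 with them
  (so correlation pruning cannot substitute them), mutual correlation
  ≤ 0.2 (with a bounded relaxation ladder for chemically narrow samples).
  Default weights (±1.1 … ±1.3) have near-equal magnitudes — each planted
  feature is individually consequential, hence recoverable in principle —
  and give a planted-signal SD near one log unit, so IC50 spans roughly
  three orders of magnitude and the attainable validation correlation under
  σ = 0.3 is ≈ 0.95. IC50 values are emitted in nM and round-trip exactly
  through the pIC50 conversion.
* **Docking energies** — seven simulated terms; the free binding energy is
  correlated with activity at a configurable strength (default 0.3, i.e.
  weakly informative, matching the observation that a docking-energies-only
  model explains little variance), the other six are independent Gaussians
  with realistic means on the kcal/mol scale.
* **Two-regime construction** — each class receives its own planted
  mapping with disjoint informative bits; this is the ground truth behind
  the cross-class degradation experiment (within-class R high, cross-class
  R collapsing toward 0).

What the generator does **not** emulate: congeneric-series activity cliffs,
measurement heteroscedasticity across assays, 3D/conformational effects,
and any real binding physics in the energy terms. Passing tests therefore
demonstrate that the pipeline recovers planted structure under honest
noise, not that it would reach the same accuracy on a particular
experimental series.

## Study sizes and typical results

The recovery study uses 128 compounds per run (80/20 split → 103/25),
ten seeds; the cross-prediction study uses 64 compounds per class. At these
sizes the full pipeline attains mean held-out validation R ≈ 0.90 with
≈ 88% of planted features recovered, and the cross-class correlation
collapses below 0.4 while within-class whole-set models stay above 0.85 —
the qualitative transferability failure expected between chemotypes. These
numbers are recomputed, not quoted, by `scripts/acceptance.py` and the
acceptance tests.

## Known limitations

* CFS-style selection admits signal-carrying *proxies* — descriptors
  correlated with combinations of truly informative bits. Backward
  elimination rationally keeps them (their removal costs CV R), so the
  selected set typically contains 0–3 such proxies alongside the planted
  features; they inflate the selected-set size, not the error.
* A feature whose marginal correlation with activity is near zero (e.g.
  through cancellation between correlated features of opposite effect) is
  invisible to every stage of this pipeline; the generator's identifiability
  constraints exist precisely to keep the planted ground truth outside that
  regime.
* Descriptor values, and hence selected feature names, are tied to the
  RDKit version; models should be applied under the version that trained
  them (the bundle records it).
* With ~25-compound validation sets the sampling SD of a correlation near
  0.95 is ≈ 0.03; single-seed validation R values should be read with that
  uncertainty in mind.
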