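# Methods

## Problem setting

`ehrisk` predicts whether a patient carrying a post-traumatic stress
disorder (PTSD) diagnosis will acquire an alcohol/substance use disorder
(ASUD) code within 90 days of an index encounter, using the coded events of
the preceding year — diagnoses grouped to 3-character ICD prefixes,
medications mapped to DrugBank identifiers, abnormal lab results — together
with static features: demographics, zip-linked neighbourhood social
determinants of health (SDoH), and psychotherapy status extracted from note
text. On top of the classifiers it implements a perturbation-based
relative-contribution (RC) analysis that ranks features as risk- or
protective-associated.

## Cohort rules

A case has an ASUD code in `(index, index + 90]`; a control has none. The
index date is the latest encounter strictly after the first PTSD code and
strictly before the first ASUD code whose 90-day outcome window is
observable (an ASUD event inside the window, or the patient's record
extending past the window's right edge — otherwise the patient is excluded
for insufficient follow-up). Patients with ASUD on or before the first PTSD
day are excluded. "3 months" is fixed at 90 days and "one year" at 365 days
for determinism; the outcome interval is half-open/closed `(index,
index+90]` and the lookback closed `[index−365, index]`. The one-year
ASUD washout before the index is checked explicitly, although with a single
index per patient it is implied by the before-first-ASUD rule. All rules
operate on day differences, so shifting a whole record in calendar time
changes nothing.

## Models

Visit content is embedded as the **sum** of its token embeddings (order-free
by construction); static tokens join the index-date visit. Three
classifiers share this input:

* **TLSTM** — a stacked time-aware LSTM. Before each gate update the
  previous cell memory `c` is decomposed into a learned short-term part
  `C_S = tanh(c W_d + b_d)` and the remainder; the short-term part is
  discounted by `g(Δ) = 1/log(e + Δ)` with Δ the gap in days:
  `c* = c − C_S·(1 − g(Δ))`. This algebraic form makes the zero-gap limit
  (`g(0)=1`) bit-exact: the cell reduces to a plain LSTM, which the tests
  pin. The discount is applied at every stacked layer with the same Δ.
* **RETAIN** — reverse-time attention. Two recurrent encoders run over the
  visit embeddings in reverse chronological order; one yields a scalar
  visit-level attention α (softmax across visits), the other a
  coordinate-level gate β = tanh(·). The context `Σ_i α_i (β_i ⊙ v_i)`
  feeds a logistic head, and α/β are returned for interpretation. A
  configured depth of `n_layers` is split evenly between the two encoders
  (8 → 4+4, the desk-scale 2 → 1+1).
* **Logistic baseline** — bag-of-token counts plus the standardized
  continuous SDoH vector through scikit-learn logistic regression; its
  coefficients drive the SDoH analysis.

Reference (full-scale) hyperparameters: embedding 128, hidden 128, dropout
0.2, 8 layers, vocabulary capacity 30 000, early-stopping patience 3,
metrics over 5 repeats. Dropout is applied between recurrent layers and
before the output head, not to the token-level inputs — deleting sparse
presence signals at the input makes the small-scale models markedly worse.
Forget-gate biases initialise at +1 (standard memory-retention trick); all
other parameters are uniform ±1/√H. The recurrent stack, attention and
optimiser run on a small reverse-mode automatic-differentiation engine
written in numpy (`ehrisk/_nn.py`), float64 throughout, with gradients
verified against central differences.

Training minimises binary cross-entropy with Adam (default lr 1e-2, batch
128); early stopping halts after 3 epochs without a validation-AUROC
improvement and restores the best-validation weights. Splits are
patient-level 8:1:1 with a seeded shuffle.

## Contribution analysis

For a trained model, the feature contribution (FC) of token *t* for one
patient is the occlusion delta `p(sequence) − p(sequence without t)`; by
default every occurrence is removed at once (a per-occurrence mode sums the
single-visit deltas instead). Per patient, FCs are normalized by the sum of
**absolute** FCs over the patient's features, so signed contributions
cannot cancel into a tiny denominator and heavy utilisers do not dominate;
a patient with all-zero FCs maps to zeros. Per feature,

    RC = median(normalized FC, cases) / median(normalized FC, controls),

undefined (reported, never dropped) when the control median is zero. All
RCs are rescaled so the grouped PTSD token `DX:F43` has RC exactly 1;
RC > 1 reads risk-associated, RC < 1 protective. Significance is a
two-sided Wilcoxon rank-sum on the two FC samples — exact enumeration of
midrank assignments for combined n ≤ 10, tie-corrected and
continuity-corrected normal approximation otherwise — with
Benjamini–Hochberg FDR across features at α = 0.05. Reports are ranked by
q ascending, then total support, then name; features need 10 cases and 10
controls carrying them.

The SDoH analysis refits the logistic baseline on (default) 10
re-randomized splits and t-tests each covariate's mean coefficient against
zero (df = repeats−1); a zero-variance coefficient sequence reports p as
NaN rather than zero.

## Synthetic cohort generator

Because the motivating clinical database is not distributable, every stage
runs against a generator that emulates its statistical structure: visits
from a homogeneous Poisson process (12/patient-year over 2 years),
per-visit Bernoulli token occurrence over a small vocabulary of diagnosis /
drug / abnormal-lab events, zip-linked SDoH features uniform on [−1,1] over
40 zip codes, and notes whose sentences phrase a therapy keyword as ongoing
or declined/historical. The outcome is a logistic draw on planted log-odds:
a +2.0 risk drug, a −2.0 protective drug, a 0.0 null drug (the benchmark
trio), a moderate field of clinical effects (±0.8–2.0), SDoH coefficients,
and protective psychotherapy-status effects. The chronic PTSD diagnosis is
re-coded at ~7% of visits (≈55% presence in a 1-year lookback) and carries
a +1.0 presence effect, making it a stable moderate reference for the RC
scaling — the analysis presumes its reference is a common feature with a
real, intermediate contribution. Effect sizes were set so the true linear
predictor's discriminability (Bayes AUROC ≈ 0.93) matches what the
published full-scale models achieve on real data, and the base logit
centres the case fraction near one half. For cases, the first ASUD code is
placed uniformly within the 90-day window after the generator's index
encounter, and later pre-diagnosis visits are dropped so the cohort rules
recover exactly that encounter. Ground truth (outcome, exposures, linear
predictor, therapy status) is stored apart from the timelines.

What the generator does **not** emulate: realistic ICD/DrugBank vocabulary
breadth, coded-event correlations beyond the shared outcome, visit-rate
differences between sick and healthy patients, free-text beyond keyword
structure, measurement error in SDoH tables. Passing tests therefore show
the pipeline's machinery and statistics behave as specified — not that the
models would reach these numbers on real EMR data.

## Scale of the shipped experiments

Tests and the acceptance script run a desk-scale configuration: 4 000
patients, 2 recurrent layers, 32-dimensional embeddings/states, 25 epochs
maximum; the replicate study uses 20 independent cohorts of 1 000 patients
with 32-dimensional models. These sizes are the package's standard
benchmark; the full-scale 8×128 configuration is available through
`ModelConfig` defaults.

## Psychotherapy NLP

Candidate sentences are selected by case-insensitive keyword match (CPT,
PE, EMDR, CBT phrases), then classified active/inactive by cosine
similarity to exemplar anchor sentences: active needs the best active
anchor to beat the best inactive anchor (margin 0) and to reach similarity
0.5; ties fall to inactive. The shipped embedder is a deterministic hashed
bag-of-words (md5 feature hashing into 768 signed dimensions) so the test
path needs no trained weights; any deterministic text→vector callable — a
pre-trained sentence transformer, for instance — satisfies the same
contract. Notes after the index date are ignored. Negation is handled
through the inactive anchors, not a rule engine.

## Known limitations

* **Null features can reach significance at scale.** Normalizing FCs per
  patient divides by the patient's total absolute attribution, which is
  systematically larger for cases; any feature the model does not perfectly
  ignore — and finite-sample models ignore nothing — acquires a small
  class-location shift in its normalized FCs. The reference scaling
  corrects the RC *point estimates* for exactly this utilisation bias, but
  the Wilcoxon test is computed on the normalized FCs directly and inherits
  the shift, so with enough support a zero-effect token can be flagged
  significant (measured: 65–75% of replicates at n=1000; q≈1e−3 at n=4000,
  while the same token's *unnormalized* FCs test clean). Rankings and RC
  directions are unaffected; significance flags for weak features should be
  read with this in mind.
* Scaled RCs depend on the reference feature's stability; with a reference
  whose contribution hovers near zero the scale factor is noise (this
  motivated the generator's moderate-reference design).
* The generator's independence assumptions make the task easier than real
  EMR data at equal Bayes discriminability.
* Attribution is measured by deletion; tokens whose removal empties a
  patient's record entirely are assigned zero contribution for that
  patient.
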