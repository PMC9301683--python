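# Methods

## The analysis problem

Outpatient registries for upper-airway disease record three streams per
patient: demographics, dated visits with ICD-10 diagnosis codes, and
free-text chart notes. The analysis implemented here phenotypes each patient
from that evidence, characterizes disease groups and their overlap, and
models how diagnoses and comorbidities shape the rate of return visits.
Because such registries are access-restricted, the package pairs the
analysis with a synthetic-cohort generator whose defaults emulate a
reference hospital cohort of 5,080 rhinitis/rhinosinusitis patients; every
stage of the pipeline is exercised and validated on data it generates.

## Information extraction

Two extraction routes feed phenotyping:

1. **Code search.** Any token matching the ICD-10 lexical shape (letter, two
   digits, optional dotted subcode) — whether in the structured code field
   or written inside the note text — counts as affirmed evidence. No context
   analysis is applied to code matches.
2. **Keyword search with context validation.** Notes are split into
   sentences at `.`, `!`, `?`, and newlines (periods inside code-like tokens
   such as `J33.1` do not split), lowercased, and tokenized on
   non-alphanumeric boundaries with internal hyphens preserved. Dictionary
   keywords (single- or multi-word, matched token-exact, no stemming) are
   classified by context cues: a negation or resolved-status cue fires when
   its last token lies 1..`scope_tokens` tokens before the keyword in the
   same sentence; a family-history cue fires anywhere in the sentence.
   Precedence is negated > family > resolved > affirmed. Only affirmed
   mentions set patient flags.

Numerical/structural choices: `scope_tokens` defaults to 5, a conventional
clinical-negation window; the cue-before-keyword restriction for negation
and resolved cues is deliberate (post-keyword negations like "diabetes no
longer" read as affirmed — the conservative direction for the *resolved*
sense is accepted as a known limitation); short ambiguous keywords such as
"asa" are matched only as whole tokens. The shipped dictionary carries full
keyword lists only for diabetes and NERD plus the single-term EHR concepts
(allergy, immunodeficiency, nasal polyps, chronic rhinosinusitis); all other
concepts are ICD-prefix scaffolds meant to be extended through a user
dictionary file.

## Phenotype definitions

Patient-level flags follow fixed clauses over the union of coded and
in-text codes plus affirmed keyword concepts:

- AR ⇔ any J30; NAR ⇔ any J31; any CRS ⇔ any J32 or J33; CRSwNP ⇔ any J33;
  asthma ⇔ any J45 (J45.0/J45.1/J45.9 all qualify).
- CRSsNP ⇔ J32 present ∧ no J33 ∧ no affirmed nasal-polyp text (mutually
  exclusive with CRSwNP by construction).
- With k = number of J01-coded visits and *no CRS evidence* = no J32 ∧ no
  J33 ∧ no affirmed "chronic rhinosinusitis" text:
  ARS ⇔ 1 ≤ k ≤ 3 ∧ (k < 2 ∨ gap(1st, 2nd) ≤ 90 days) ∧ no CRS evidence;
  RARS ⇔ k ≥ 2 ∧ no CRS evidence; CRS AE ⇔ k ≥ 1 ∧ J32 ∧ no J33;
  CRSwNP AE ⇔ k ≥ 1 ∧ J33; any CRS AE = CRS AE ∪ CRSwNP AE.
- Composites: allergy ⇔ J45.0 ∨ J30 ∨ affirmed "allergy";
  immunodeficiency ⇔ B20 ∨ D80–D84; the or-suspicion variant additionally
  accepts the affirmed keyword; NERD is purely keyword-driven.

Design choices made where the definitions were genuinely open:

- The no-CRS clause of ARS/RARS is read **conjunctively**, making the acute
  groups disjoint from CRS (consistent with how the groups are tabulated);
  a `strict_or` flag provides the literal disjunctive reading.
- "Any CRS AE" includes CRSwNP AE (union reading); `include_crswnp_ae=False`
  restricts it to the J32-only definition.
- The rhinitis/rhinosinusitis entity count treats **J01 presence** as the
  acute entity, so a patient with J01 + J32 carries two entities. This is
  required for internal consistency: acute-exacerbation patients are, by
  definition, multi-entity, and every included patient (≥ 1 qualifying code)
  has entity count ≥ 1 even when >3 J01 visits disqualify the ARS label.
- "Other diseases" counts 17 non-rhinitis categories (asthma, allergy, NERD,
  diabetes, other chronic respiratory, obesity, mental, memory,
  cardiovascular, cancer, musculoskeletal, obstructive sleep apnea, mouth
  breathing, reflux, chronic otitis media, tonsil disease,
  immunodeficiency-or-suspicion); the set is configurable.
- The 90-day gap rule uses inclusive calendar-day difference.

Adding evidence is monotone for accumulative flags (False→True only); the
exclusion clauses make exactly CRSsNP, ARS, RARS, and CRS AE able to flip
True→False when J32/J33/polyp/chronic-text evidence arrives — the test
suite asserts precisely this asymmetry.

## Cohort characterization

Percentages are displayed to one decimal, round-half-up; raw values are kept
internally. Age is taken at the first qualifying visit (configurable
reference). Inter-visit interval statistics use only patients with ≥ 2
visits. Visit frequency has two definitions: visits/year from first to last
visit (denominator = span; undefined below two visits or at zero span, and
deliberately using n rather than n−1 in the numerator) and visits/year from
first visit to the study end. Years use 365.25 days. Three-set overlap
partitions are exact counts of the seven disjoint regions; a plain
matplotlib three-circle rendering is provided.

## Visit-burden models

**Gap-time construction.** The clock resets at each visit: a patient with
visits d₁ < … < d_k contributes k−1 event intervals (gap dᵢ₊₁−dᵢ, prior
visit count i) and one censored interval to the study end. Phenotype flags,
age at first visit, and sex are constant within patient; prior visit count
is the only interval-varying covariate, entered linearly. The construction
is isolated so a calendar-time (counting-process) variant could be added.

**Cox fit.** Partial-likelihood maximization with the Efron tie correction
(gap days are integers; ties are certain) and Wald 95% intervals, delegated
to a standard survival-regression backend and cross-checked in the test
suite against an independent reference implementation on a frozen fixture
(coefficients and standard errors agree to 1e-5). Constant covariates are
dropped with a warning.

**Penalized fit.** A pure-L1 elastic-net Cox path over 100 log-spaced
penalties from the null-model λ down to 10⁻³ of it. Cross-validation is
K-fold (default 5) with folds drawn at the **patient** level, so one
patient's intervals never straddle the split; folds without events are
redrawn. The CV criterion is the Verweij–van Houwelingen partial-likelihood
deviance (full-data deviance minus training-fold deviance at the
training-fold coefficients), normalized per test-fold event; λ_1se is the
largest penalty whose mean CV deviance is within one standard error of the
minimum. At vanishing penalty the path coefficients agree with the
unpenalized fit to 1e-4 on tie-free data (asserted in tests).

## The synthetic cohort generator

What it emulates: index sampling uniform over the months of
2005/2007/2009/2011/2013 with follow-up to 2019-09-30; age at index from a
normal (mean 33.6, SD 20.7 years) truncated to [0, 100]; 56.1% female;
concept prevalences set to the reference cohort's marginal proportions
(e.g. J30 33.5%, J31 27.5%, J32 20.7%, J33 10.9%, J01 27.2%, asthma 44.4%,
NERD 3.9%); visits from a homogeneous exponential renewal process with
per-patient rate = base (0.18/year) × per-concept multipliers, calibrated so
the cohort mean is about 5 visits per patient; multipliers > 1 for chronic
sinonasal disease and systemic comorbidity, < 1 for allergic rhinitis and
acute presentations, matching the direction structure the burden models are
meant to recover.

Key mechanisms:

- **Inclusion.** Patients must carry ≥ 1 qualifying code (J30/J31/J32/J33/
  J01). Rejection sampling with the five qualifying prevalences rescaled by
  the fixed point c = 1 − Π(1 − c·tᵢ) makes each conditional marginal in the
  accepted cohort equal its configured value exactly.
- **Comorbidity clustering.** Concepts are drawn from a sequential-logistic
  model: pairwise log-odds adjustments shift a concept's logit for each
  already-sampled partner, and intercepts are re-solved numerically (Monte
  Carlo prefix calibration, fixed internal seed) so configured marginal
  prevalences are preserved under the dependence. Default edges connect
  only comorbidity concepts — never the qualifying codes, keeping the
  inclusion rescaling exact — with strong clinically motivated pairs
  (asthma–NERD, cardiometabolic axis), a high-prevalence multimorbidity
  clique, and a weak background association; weights are calibrated so the
  "other diseases" bucket distribution approximates the reference cohort's
  (10.4/18.0/17.6/17.0/37.0% for 0/1/2/3/≥4). With user-supplied edges
  touching qualifying concepts, configured values act as base probabilities
  rather than exact marginals.
- **Planting.** Each sampled code-backed concept is stamped on ≥ 1 visit
  (each visit with probability 0.35; J01 instead follows an episode model,
  1 + Poisson(0.35) visits, so recurrent-ARS rates stay realistic). Sampled
  concepts also appear as note mentions: keyword-only concepts (NERD,
  allergy, immunodeficiency suspicion, nasal-polyp and chronic-CRS text)
  always affirmed — a non-affirmed mention would be unrecoverable and bias
  the marginal — while code-backed concepts draw polarity from the
  configured affirmed/negated/family/resolved rates (default
  0.80/0.10/0.05/0.05). Unsampled keyword concepts receive non-affirmed
  distractor mentions at rate 0.10. Notes embed each mention's keyword in a
  polarity-matched sentence template.
- **Determinism.** One master seed; each patient's stream derives from
  (seed, patient index). Same config and seed ⇒ byte-identical output.

What it does **not** emulate, hence what passing tests do not show about
real data: clinical language (templates are synthetic and language-neutral;
no negation ambiguity, misspellings, or morphology), coding noise (planted
codes are always correct, so extraction recall on real charts is not
measured), dependence between qualifying diagnoses and comorbidities (the
NERD-within-CRSwNP enrichment of real cohorts is not reproduced; the
synthetic NERD share of CRSwNP patients is near its marginal), visit-rate
heterogeneity beyond concept multipliers (no frailty), department-specific
referral dynamics, and phenotype onset during follow-up (concepts are
whole-record). Age is drawn around the cohort mean rather than matched to
the pediatric share, and the emulated follow-up (from uniformly sampled
index years) is longer than the reference cohort's reported mean — the
generator favours internal consistency of its sampling design over matching
every marginal simultaneously. Derived-group shares that depend on joint
structure (CRSsNP ≈ 19–20% here vs 17.9%, acute-subgroup shares) are
approximate emulations, not targets.

## Problem sizes and tolerances

The test suite validates extraction against a brute-force cue/keyword
oracle (exhaustive placements to 10 tokens, randomized to 30), phenotyping
against an independent clause evaluation on 10,000 random evidence sets,
overlap partitions against full enumeration, Cox estimates against frozen
reference-implementation values (1e-5), planted rate-ratio recovery (true
HR 2.0 recovered within [1.7, 2.35] at 2,000 patients), null CI coverage
(≥ 90/100 replicates at 150 patients), penalized-path behaviour (empty
model on ≥ 95% of all-noise designs; a planted HR-2 predictor always
selected), and round-trip prevalence recovery at 2,000 patients within
exact binomial 99% intervals. Simulation sizes are chosen so the full suite
completes in well under a minute per heavy check while keeping Monte Carlo
error far inside the asserted bands.
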