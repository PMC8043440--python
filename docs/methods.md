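# Methods

## Problem setting

Routine radiograph reports are free text; counting "how many fractures were
seen this spring" therefore requires a report-level binary decision —
*fracture affirmed* versus *not affirmed* — before any incidence statistics
can be computed. `fracsurv` implements that decision with deterministic
rules, evaluates it against reference annotations, and screens stratified
yearly counts for decreases with a deliberately conservative Poisson test.
The target design is a single-site surveillance comparison: a fixed
March 18 – April 30 window per year, five baseline years (2015–2019) versus
a test year (2020), outpatients referred from orthopedics/trauma or
pediatrics, radiographs of hand/wrist, elbow, shoulder, ankle, knee and
pelvis/hip, with age strata <18, 18–65 (both ends inclusive) and >65 years.

## The rule engine

Stages: cleansing (whitespace normalization, de-hyphenation of line breaks,
offset map to the raw text), contextualization (section split on the header
cues *Indikation:/Fragestellung:/Anamnese:*, *Befund:*, *Beurteilung:*;
sentence split on terminal punctuation with abbreviation protection for
*V.a.*, *Z.n.*, *i.p.* etc., and internal dots), concept recognition
(lower-cased lexicon; substring-mode lexemes *fraktur*, *bruch*, *fissur*
match inside compounds, with a token blocklist — *Abbruch*, *Durchbruch*,
*Unterbrechung*, ... — suppressing false compounds), and polarity
resolution in the NegEx tradition: pre-negation triggers scope forward over
a 5-token window (the classic convention; configurable per trigger in the
CSV resource), post-negation triggers scope backward, uncertainty triggers
both ways, termination tokens (*aber*, *jedoch*, ...) cut scopes,
pseudo-triggers (*ohne weiteres*) inert the trigger they contain, and a
recommendation trigger (*empfohlen*) demotes same-sentence mentions to
uncertain. Precedence per mention: negated > uncertain > affirmed.

Report rule: affirmed iff ≥1 affirmed mention. This "any-affirmed" rule is
deliberate: a report can contain both an excluded and a confirmed fracture
at different sites, and the confirmed one counts. Mentions in the
indication section are discarded — the referring question *"Frage nach
Fraktur"* must never count; a headerless report (or preamble before the
first header) is treated entirely as findings, so content is never dropped.
Suspected/uncertain mentions map to *not affirmed* at report level,
matching the annotation policy of counting only fractures confirmed with
certainty.

Design choice: the engine is rule-based end to end. The stages mirror what
commercial clinical-NLP pipelines do, but rules keep every decision
auditable (the per-match audit JSONL records span, lexeme and polarity) and
make the whole acceptance surface deterministic. The shipped fracture
synonym list and trigger inventory are reconstructions appropriate for the
template language below; both are plain CSV resources and hot-swappable for
richer site-specific vocabularies.

## Evaluation statistics

Confusion counts take "affirmed" as the positive class; precision, recall
and F1 follow the usual definitions, with undefined denominators surfaced
as explicit `None` (never silently 0, which would corrupt aggregate means).
Cohen's κ = (p_o − p_e)/(1 − p_e) with the two-class marginal expectation;
identical constant vectors define κ = 1. Consensus adjudication requires
the third reader to cover exactly the disagreement set. The overall engine
score is the unweighted arithmetic mean of per-year consensus F1 values —
with the reference per-year values 0.82 and 0.79 this displays as 0.81 —
and display rounding is half-up at 2 decimals (0.805 → 0.81), with decimal
noise absorbed at 10 places first; stored values keep full precision.

## The conservative Poisson decrease test

Counts per stratum-year are modelled iid Poisson(λ). With n baseline years,
λ̂ is the MLE (the mean); the test evaluates the exact lower tail at the
asymptotic 95 % CI lower bound λ̂_low = λ̂ − z₀.₉₇₅√(λ̂/n) (exact quantile
1.959964..., not the rounded 1.96; the difference is far below reporting
precision). p = P(X ≤ k | λ̂_low) via the regularized incomplete-gamma
identity (`scipy.special.pdtr`), never a normal approximation — the unit
suite checks agreement with brute-force pmf summation to 1e-12 up to
rate 50, k 200. λ̂_low = 0 yields p = 1 by convention, flagged. When the
observed count exceeds λ̂ the lower-tail p is still returned with a
direction note; an explicitly labelled exploratory `increase_test`
(upper tail at λ̂ + z√(λ̂/n)) is provided as this package's own symmetric
extension. p-values are reported as "< 0.001" below 0.0005, else at three
half-up decimals. No multiple-testing correction is applied across the 20
table rows; each stratum is a separate monitoring question.

Testing at λ̂_low rather than λ̂ makes the test strictly under-sized: in the
5000-replicate null simulation (all six counts iid Poisson(λ), λ ∈ {40,
150, 300, 950}) the rejection rate at p < 0.05 stays near 0.01. The price
is power at the margin: a true ~21 % decrease from a baseline mean of 140
(the 18–65 fracture stratum's configuration) yields p ≈ 0.047 at the table
counts themselves, i.e. the stratum sits essentially on the decision
boundary, and under resampling of both baseline and test year it is flagged
in only ~60 % of replicates. This is an inherent property of the stated
construction at those rates, not an implementation artifact; the clearly
separated strata (total, under-18, hand/wrist, most examination rows) are
flagged in ≈90–100 % of replicates.

## The synthetic corpus generator

The generator defines the study conditions for all stochastic tests. Yearly
per-stratum report counts are Poisson(exam_rate); each report's true
fracture status is Bernoulli(prevalence); exam dates are uniform over the
44-day window; ages uniform within stratum (1–17, 18–65, 66–95); under-18
reports are referred from pediatrics, others from orthopedics/trauma.

The published count tables give only age-group and region *marginals*, not
the joint strata the generator needs, so defaults use an independence
(product) model: exam_rate(r, a) = E_r·E_a/E_total and prevalence(r, a) =
P_r·P_a/P_total, which reproduces both marginal tables in expectation (up
to the printed tables' own ≤2.6 % internal inconsistency between region
sums and totals). Baseline years 2015–2019 share the 2015–2019 mean rates;
2020 uses the 2020 column.

Text is realized from a versioned German template bank; every template
carries trace tags, and the gold label is derived from the generation path
(true fracture + certain phrasing → affirmed; anything else → not
affirmed), never from the text. Style rates (defaults chosen to emulate
clinically plausible report language at the published engine-accuracy
level): `negated_mention_rate` 0.5 (non-fracture reports still mentioning a
negated fracture), `uncertainty_rate` 0.1 (true fractures phrased as
suspected, gold not-affirmed), `recommendation_rate` 0.7 (uncertain reports
adding a CT/MRI recommendation), `distractor_rate` 0.2 — the probability of
a *hard* realization: an out-of-lexicon affirmed phrasing
(*Kortikalisunterbrechung* with *Stufenbildung*) that the engine misses, or,
for non-fractures, 50/50 a blocklist compound (*Abbruch der Untersuchung*)
or an out-of-lexicon negation (*hat sich nicht bestätigt*) that the engine
false-positives on. By construction the engine agrees with gold exactly on
all easy templates (distractor-free corpora give F1 = 1.0), and the default
mix lands engine-vs-gold F1 ≈ 0.77–0.80, inside the published per-year
0.76–0.82 band. Expected arithmetic at prevalence ≈ 0.31: recall 0.8
(1 − distractor_rate), precision ≈ 0.76, F1 ≈ 0.78.

What the generator does **not** emulate: real lexical diversity (a few
dozen templates versus open clinical language), multi-site reports with
mixed findings, typographical noise, post-surgical follow-up phrasing, or
correlations between region, age and phrasing style. Passing tests
therefore demonstrate the pipeline's correctness and the statistics'
behaviour under controlled conditions — not the engine's accuracy on real
archives, which would require site-specific lexicon extension and a human-
annotated sample.

## Numerical and procedural choices

- All spans are 0-based half-open on the cleansed text; the raw→cleansed
  offset map is kept for display and audit.
- Window endpoints (March 18, April 30) are inclusive on both sides; age 65
  belongs to the middle stratum.
- Duplicate report ids are fatal in I/O (silent double counting would
  corrupt the Poisson counts); malformed records are skipped with logged
  warnings.
- Determinism: a single integer seed drives corpus generation (strata are
  visited in sorted order, so output is independent of dict ordering); the
  classifier is stateless and deterministic; CLI reruns are byte-identical.
- Simulation sizes: the null-size check uses 5000 replicates per rate; the
  end-to-end detection check runs the full generate→classify→surveil
  pipeline over 100 seeds (test suite) / 40 seeds (acceptance script) at
  the default corpus scale of ≈5400 reports.

## Known limitations and observed discrepancies

- Published performance-table rows are not all internally consistent: the
  consensus-year rows' printed F1 (0.82 for 2019, 0.79 for 2020) differ
  from the values their own printed counts imply (0.83, 0.80). Metric
  recomputation is asserted only on the self-consistent rows; the overall
  F1 uses the printed consensus values as inputs.
- The published "conservatively estimated expected number of counts
  (95 CI)" interval columns are asymmetric around λ̂ and match no CI
  construction stated with the method; they are not reproduced.
- The published over-65 p-values (0.972 examinations / 0.442 fractures)
  match the stated construction almost exactly with the two rows swapped
  (our method: 0.436 and 0.972 respectively), suggesting a table
  transposition; the stated method is implemented verbatim.
- Annotator-vs-annotator κ (reported ≈0.85–0.91) cannot be recomputed:
  the annotator cross-tabulation is not published. The κ implementation is
  instead verified against an independent library on simulated raters.
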