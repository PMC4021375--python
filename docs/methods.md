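# Methods notes

This note records the model, the conventions chosen where the underlying
procedure is genuinely open, the defaults and why they hold, and what the
synthetic data does and does not establish.

## Variant model and coordinates

A non-frameshift indel (NFS-Indel) inserts or deletes whole amino acids.
All coordinates are 1-based; intervals are closed. A deletion of n residues
at position p removes reference residues [p, p+n−1] and must match the
reference sequence exactly. An insertion at position p places the new
residues *before* the residue at p (valid positions 1 … L+1). Indels are
restricted to 1–6 residues (3–18 coding bases): longer in-frame events are
rare enough that a categorical learner has too few examples per cell, and
the readers reject them with a distinct error rather than silently binning
them.

## Physico-chemical codes and semantic bins

Each amino acid carries four small integer codes: volume 1–5,
hydrophobicity 0–3, charge −1…1, polarity 0–1, obtained by binning
literature property scales. The 20×4 table is hard-coded and fidelity-tested
cell by cell. Semantic labels are assigned to codes by rank order (lowest
volume code → "very_small", …). For an indel we compute both the **average**
and the **total** of the codes over its residues. Semantic mapping of an
average rounds half away from zero to the nearest code; a **total** is first
divided by the indel length so it lands on the same per-residue code scale
(the label scale is only defined there), while the raw total is kept for the
perturbation computation. Codes that round outside the scale are clamped to
the nearest end with a logged warning.

## Local perturbation

For an indel i and a scope s the perturbation is

    d_avg = x̄_s − x̄_i        d_tot = Σx_s − Σx_i

for x ∈ {volume, hydrophobicity, polarity, charge}. Scopes, for an indel of
n residues:

* **site** — the residues that take the indel's place: for a deletion the n
  residues immediately downstream of the deleted span (falling back to the
  upstream n at the C-terminus; a deletion spanning the whole protein is an
  annotation error); for an insertion the n reference residues starting at
  the insertion position.
* **environment** — the n residues flanking the indel on *each* side (2n
  total, truncated at protein ends). "Flanking" is anchored on the deleted
  span, or on the insertion point, so for a deletion the right flank
  coincides with the site.
* **region** — 2n residues per side (4n total, truncated).

The n-per-side reading of "n flanking residues" is a convention (n-total is
the other possible reading); it is used consistently and documented here so
results can be compared across conventions. d is rounded half away from
zero and clamped to [−2, +2], giving the five ordinal labels two_less,
one_less, equal, one_more, two_more. The numeric d is antisymmetric under
swapping the indel residues with the site residues, and the self-case
(site identical to indel) is always "equal" — both are enforced by tests.

## Structural bins and aggregation

Per-residue tracks are aggregated over the **site span** by arithmetic mean
(the natural choice for multi-residue indels; the defining sources only
state thresholds for single values). Bins:

* disorder probability P: structured (P < 0.4), semi_disorder
  (0.4 ≤ P ≤ 0.7), disorder (P > 0.7). The boundary points are assigned to
  the middle bin — the strict inequalities of the source thresholds leave
  them unassigned, and a deterministic convention is required.
* solvent-accessibility value R_v: five left-closed bins of width 30,
  [0,30) fully_buried … [120,∞) fully_exposed; R_v = 30 is therefore
  "buried".
* secondary structure: the window is the site span widened by one residue
  per side — the minimal window that can witness a transition. All-coil →
  coil; coil plus exactly one non-coil state → "two" (transition zone);
  otherwise the majority non-coil state, ties to strand (strand loss is the
  more disruptive event, so the tie resolves toward the stronger signal).
* relative indel position: span midpoint (deletions) or the half-position
  between the flanking residues (insertions), divided by protein length;
  ≤ 0.10 N-terminal, ≥ 0.90 C-terminal.

Conservation and functional flags are closed-interval intersections of the
site span with the annotated intervals (conserved residues: any site
residue flagged).

## Rule learning

Rule induction is a propositional specialisation of bottom-clause guided
ILP search: every example is fully described by single-valued categorical
attributes, so a seed example's bottom clause reduces to its
(parameter, value) pairs and rule growth is a beam search over conjunctions
of those literals. Score = positives − negatives covered, computed on the
full training set. Acceptance requires ≥ minpos positives (default 6) and
≤ noise negatives (default 0). States already satisfying the noise bound
are not specialised further — at noise = 0 adding literals to a
zero-negative rule can only shrink the positive coverage, so this cannot
lose the optimum; on instances small enough to enumerate, the search
provably returns the exhaustive optimum (tested). Ties are broken toward
fewer literals, then schema order, for determinism.

The outer loop is sequential covering: uncovered positives, in an order
shuffled under the run seed, serve as seeds; each accepted rule removes the
positives it covers; the loop stops when all positives are covered or no
remaining seed yields an acceptable rule (≤ n_pos iterations, so
termination is guaranteed). Rules whose covered positive set is a subset of
an earlier rule's are discarded as redundant. Defaults beam_width = 5 and
max_literals = 6 bound the search; both are configurable. Prediction is
"deleterious iff at least one rule fires"; the rules characterise only the
deleterious class, so uncovered vectors default to neutral.

## Parameter selection

Discriminative power x = Σᵢ |fnᵢ − fpᵢ| over a parameter's values, with
within-class relative frequencies and no smoothing (a value absent from a
class contributes its full frequency in the other class); x ∈ [0, 2].
Association between categorical parameters is bias-uncorrected Cramér's V —
a standard [0, 1] categorical association compatible with cutoff grids in
0.5–0.9; a constant parameter gets V = 0 with a warning. Selection is a
greedy pass in descending x (ties by schema order): keep the parameter,
drop every not-yet-processed parameter with V ≥ the correlation cutoff,
then drop kept parameters with x below the x cutoff (defaults 0.7 and 0.2).
The wrapper grid re-runs selection plus cross-validated learning per cutoff
cell and also reports mean training accuracy, so train-vs-test curves as a
function of parameter count expose over-fitting.

## Evaluation

Confusion statistics follow the standard 2×2 formulas; MCC uses
(Tp·Tn − Fp·Fn) over the square-root product of the four marginals. Any
zero denominator yields NaN, never a silent 0. Percentages are rendered to
two decimals, half away from zero. Cross-validation uses *stratified*
random folds: the cohorts this tool targets are deliberately class-balanced,
and stratification preserves that balance in every fold (plain random
splitting is the obvious alternative; stratification is the documented
deviation-by-convention). Per-fold learner seeds are derived from the run
seed, the fold partition is asserted to be disjoint and exhaustive on every
run, and the rule set of the best-accuracy fold is retained as the "final"
rule set. Chi-square class comparisons are Pearson tests without continuity
correction at the 95% level. The allele-frequency reliability analysis bins
user-supplied frequencies at width 0.1 and correlates bin midpoints with
the percent predicted deleterious; empty bins are excluded with a notice,
and r is NaN when fewer than two varying bins remain.

## Synthetic data

`generate_dataset` draws vectors from a per-parameter background
distribution (uniform by default), forces positives to satisfy planted
literal conjunctions round-robin, and rejection-samples negatives until
they satisfy no planted rule (hard cap 10⁴ attempts per record, so
termination is guaranteed and an impossible background raises). With zero
label noise the data is perfectly separable by the planted rules, which
grounds the recovery tests: the learner must reproduce the planted
extension on training data and generalise in cross-validation. The standard
study condition used by the tests and the acceptance script is 15
parameters of arity 2–4, two 3-literal planted rules, and 200 + 200
records — large enough that sub-conjunctions of a planted rule almost
surely cover background negatives (forcing the learner to find the full
conjunction) while keeping a full 10-fold CV of the pipeline under a
minute on one core.

What the synthetic data does **not** emulate: the marginal parameter
distributions, linkage between structural parameters (e.g. disorder and
RSA are strongly coupled in real proteins), label noise from curated
databases, and cohort-level ascertainment. Passing tests therefore
establish the correctness of the machinery, not the field performance of
the learned rules on real cohorts — the latter depends entirely on the
user's annotations.

`generate_protein_context` builds proteins from piecewise-constant segments
(secondary structure, disorder, RSA, conservation) with explicit annotation
intervals and variants placed to hit requested feature combinations; tracks
are exact segment values rather than noisy predictions, which is what makes
category-forcing end-to-end tests possible.

## Known limitations

* The tool operates purely in protein space; mapping from genomic (VCF)
  coordinates, and producing the upstream disorder/RSA/secondary-structure
  predictions or alignments, are out of scope — their outputs are inputs.
* Insertion anchoring (before-residue) and the site/flank conventions above
  are choices; data prepared under different conventions must be converted.
* The learner is propositional: no relations between examples, no variables
  beyond the implicit example, no recursion.
* Rule sets only describe the deleterious class; "neutral" is a default,
  not a characterisation.
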