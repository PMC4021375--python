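# indelrules

Interpretable rule learning for the phenotypic effect of protein
non-frameshift indels (NFS-Indels).

## The problem

Small in-frame insertions and deletions — multiples of three nucleotides,
adding or removing 1–6 whole amino acids — are a frequent cause of Mendelian
disease, yet most variant-effect predictors output only an opaque score.
`indelrules` takes the opposite approach: it characterises each NFS-Indel
with a panel of categorical structural, functional, physico-chemical and
evolutionary parameters, then learns an explicit set of human-readable
rules of the form

```
deleterious (A) if secondary_structure (A, strand), block (A, true),
                   local_perturbation_region_polarity_total (A, equal),
                   relative_indel_position (A, middle).
```

A variant is predicted deleterious when at least one rule fires; the firing
rules *are* the explanation. The intended users are method developers and
variant analysts who already have per-residue annotations (disorder
probability, solvent accessibility, secondary structure, conservation,
domain intervals) and want a transparent classifier over them.

## The method

1. **Annotation.** Each variant is described by 45 categorical parameters:
   conservation and functional-site overlap flags; semantic bins of the
   indel's own volume/hydrophobicity/polarity/charge (average and total of
   the per-residue codes); the *local perturbation*
   `d_avg = x̄_s − x̄_i` and `d_tot = Σx_s − Σx_i` between the indel residues
   (i) and three widening sequence scopes (s = site, environment, region),
   binned into five ordinal categories; disorder (P < 0.4 / 0.4–0.7 / > 0.7),
   RSA (five bins of width 30), secondary-structure location (including a
   "two" transition category), relative position, length, and
   proline/glycine content.
2. **Parameter selection.** Discriminative power
   `x = Σᵢ |fnᵢ − fpᵢ|` (sum over parameter values of the absolute
   difference of within-class relative frequencies), a Cramér's-V
   association filter that keeps the higher-x member of each correlated
   pair, and an optional wrapper grid that picks cutoffs by cross-validated
   accuracy.
3. **Rule learning.** Sequential covering with bottom-clause-restricted beam
   search: candidate literals come from a positive seed example, a rule must
   cover ≥ `minpos` positives (default 6) and ≤ `noise` negatives
   (default 0), and rules are scored by positives minus negatives covered.
   With `noise = 0` every rule has 100% training precision by construction.
4. **Evaluation.** Confusion statistics (accuracy, sensitivity, specificity,
   precision, NPV, MCC), per-rule coverage/precision ranking, multi-rule
   precision tables, combined precision of the rules firing on one variant
   (`Σ Tp / Σ (Tp + Fp)`), stratified k-fold cross-validation, per-parameter
   chi-square class comparison, and an allele-frequency reliability check
   (percent predicted deleterious per 0.1-wide frequency bin, Pearson r).

A synthetic-data module generates planted-rule feature tables and fully
constructed protein contexts so the entire pipeline is testable end to end
without any external resource.

## Worked example

Simulate a labelled feature table with one planted rule (40 positives,
40 negatives over four 3-valued parameters), learn rules, cross-validate
and predict:

```sh
indelrules simulate features --spec features.yaml --out table.tsv
indelrules learn --features table.tsv --minpos 6 --noise 0 --seed 1 --out rules.json
indelrules evaluate --features table.tsv --folds 10 --seed 2 --report metrics.json
indelrules predict --rules rules.json --features table.tsv --out predictions.tsv
```

prints

```
simulated 80 records -> table.tsv
learned 1 rules -> rules.json (text: rules.txt)
mean CV accuracy 100.00% over 10 folds -> metrics.json
predictions for 80 records -> predictions.tsv
```

and `rules.txt` contains the recovered planted rule with its training
coverage (40 of 40 positives, 0 negatives — hence 100% training precision):

```
# rule 1: pos_covered=40, neg_covered=0
deleterious (A) if p0 (A, a), p1 (A, b).
```

`predictions.tsv` lists, per variant, the predicted class, the firing rules
and their combined precision on the reference table:

```
variant_id  prediction   n_rules  firing_rules  total_precision
pos00000    deleterious  1        1             100.00
```

The protein-space path works the same way: `indelrules simulate proteins`
writes a FASTA plus track/interval/variant TSVs, and `indelrules annotate`
turns them into the feature table consumed by the commands above.

## Layout

- `src/indelrules/datamodel.py` — core records (variants, protein contexts,
  feature schema/datasets, run configuration)
- `src/indelrules/properties.py` — amino-acid property codes and semantic scales
- `src/indelrules/annotate.py` — feature computation
- `src/indelrules/selection.py` — discriminative power, association filter,
  wrapper grid
- `src/indelrules/learner.py` — sequential-covering rule induction
- `src/indelrules/evaluate.py` — prediction, metrics, CV, chi-square,
  allele-frequency reliability
- `src/indelrules/simulate.py` — synthetic feature tables and protein contexts
- `src/indelrules/io.py`, `src/indelrules/cli.py` — file formats and the
  `indelrules` command
- `docs/methods.md` — modelling notes, conventions and limitations
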