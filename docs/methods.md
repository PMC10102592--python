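# Methods

## Data model

Quantification is consumed at two layers.  The protein layer is a
features × samples grid of linear-scale label-free intensities (peak areas)
with explicit missingness; a MaxQuant intensity of 0 means "not observed"
and is converted to missing on read, never treated as a measured zero.  The
phospho layer is site-level: one record per (protein, residue+position,
multiplicity class), where multiplicity is the number of phosphate groups
on the quantified peptide (the `___1/___2/___3` column convention).  Each
(site, multiplicity) class is kept as a separate quantitative feature with
id `protein:S<pos>:<mult>`, because singly and multiply phosphorylated
peptide populations of the same site are distinct measurements.

The sample design is strictly paired: every patient has exactly one tumor
and one NAT sample and belongs to one subtype (IDC or ILC, five pairs each
in the emulated design).  Decoy (`Reverse`) and contaminant rows are
dropped at read time; upstream FDR control is assumed done by the search
engine and is not recomputed.

## Normalization

Per-sample global normalization is median-centering in log2 space: each
sample is shifted so that the median of its present values equals the
grand median of the pre-normalization per-sample medians.  Medians use
present values only.  The operation is idempotent, preserves within-sample
ranks, and recovers planted per-sample log2 scale biases with Pearson
r > 0.99 on a 4,000-feature no-signal cohort (the estimate error of a
sample median scales as 1/√n_features, so several thousand features are
needed for that correlation level; at a few hundred features r ≈ 0.98).
A total-intensity variant (`method="total"`) aligns log2 total intensity
instead.  Median was chosen as the default because it is robust to the
intensity-dependent missingness typical of label-free data; with the
normalization target being the grand median rather than a fixed constant,
normalizing twice is exactly the identity.

## The three-criterion screen

For each subtype separately, a feature is called **up** iff all of:

* two-tailed Welch (unequal-variance) t-test p < 0.05 between the
  subtype's tumor and NAT sample groups on log2 intensities
  (Welch–Satterthwaite degrees of freedom; fewer than two present values
  in either group makes the feature uncallable; identical zero-spread
  groups get p = 1);
* subtype mean fold change > 1.50, where the mean is the geometric mean
  of the per-patient tumor/NAT ratios (arithmetic available by config);
* strictly more than 60 % of the *present* pairs have an individual
  FC ≥ 1.50.

**down** is symmetric with 0.67 = 1/1.5 and FC ≤ 0.67.  Both percentage
criteria are strict: at five complete pairs, "more than 60 %" means 4 or
more, which is the only reading consistent with requiring more than 3 of
5 pairs.  The pair-concordance denominator is the number of pairs with
both members observed, consistent with excluding missing values
everywhere; using all pairs instead would silently penalize features with
missingness rather than flag them, which is what the separate
patient-coverage prefilter is for.  That prefilter keeps features observed
in both members of strictly more than 60 % of all pairs (7+ of 10).

The Welch test is deliberately applied in its unpaired form (tumor group
vs NAT group within a subtype) even though the design is paired; a paired
t-test on per-pair log2 differences is available behind
`ScreenConfig(paired_test=True)` but off by default.  No multiple-testing
correction is applied in the default screen; the three-way conjunction
makes it conservative — on null cohorts fewer than 2 % of features are
called (tested over 20 seeds, specified bound 5 %).

## Phosphosite processing

Sites are kept when localization probability is strictly greater than
0.75 (class I) and flags are clear; the filter is idempotent and
anti-monotone in the threshold.  Site-level screening reuses the protein
machinery on the site matrix.  The protein-level phosphorylation fold
change is the exponentiated **median** of the protein's site-level mean
log2 fold changes, with the minimum site p recorded; the median was chosen
over the mean for robustness to a single aberrant site, and the site→
protein rule is a package decision, not a claim about how any particular
published table was aggregated.  A protein counts as a differential
phosphoprotein when at least one of its sites receives a call.

## Subtype integration

Proteins differential in both subtypes are classified on the (FC_IDC,
FC_ILC) plane into both_up / both_down / the two discordant quadrants /
other, using the same 1.5 and 1/1.5 cutoffs (strict inequalities).  The
dual-layer discordance signature is the 4-tuple of states (protein-IDC,
protein-ILC, phospho-IDC, phospho-ILC), each up / down / maintained.

Three signature patterns are recognized, matched in order with all matches
reported: **G1** = (up, up, up, down); **G2** = protein not-down in both
subtypes, phospho down in IDC and not-down in ILC; **G3** = protein
maintained in IDC and up in ILC, phospho not-up in IDC and not-down in
ILC.  G2/G3 are the loosest patterns consistent with their verbal
descriptions; because a signature can satisfy both, the `matches` column
preserves every hit rather than silently resolving the overlap, and rows
fitting no pattern are reported `unassigned` rather than forced into a
group.

When states are computed from fold changes printed at two decimal places,
the comparison happens at that precision with inclusive bounds (≥ 1.50 is
up, ≤ 0.67 is down), since 0.67 is itself the rounded 1/1.5; full-precision
pipeline values use strict bounds against 1.5 and 1/1.5 so the printed-
precision rule never leaks into quantitative outputs.

## KSEA

With s̄ the mean log2 fold change over a kinase's m quantified substrate
sites and p̄, δ the mean and sample (n−1) standard deviation over all
quantified sites, the kinase score is z = (s̄ − p̄)·√m/δ with a two-tailed
standard-normal p.  δ over the full site background makes z invariant to
shifting all sites by a constant or scaling them by a positive factor.
Each (gene, site) key contributes once per kinase regardless of how many
annotation rows map it; multiplicity classes of the same site are averaged
on the log2 scale before scoring.  Site fold changes fed to KSEA are the
per-subtype geometric-mean pair fold changes from the screen, because
kinase activity is reported per subtype.  Significance requires p < 0.05
and m ≥ 3.  Kinase gene symbols are upper-cased before joining the
kinome-group table; the bundled group fixture covers common exemplars of
the ten groups and is a convenience fixture, not a complete kinome.

## Synthetic cohorts

The generator emulates: log-normal baseline abundances (log2 mean 25,
SD 2), patient random effects (log2 SD 0.3) shared between a patient's
tumor and NAT samples, within-group noise (log2 SD 0.5), per-sample scale
offsets (log2 SD 0.3), planted differential proteins (10 % of features at
fold change 3, random sign, same shift in both subtypes), planted kinase
activations applied as a common log2 shift to all annotated substrate
sites in the tumor samples of one subtype, and missing-not-at-random
dropout: per-cell dropout probability is a logistic function decreasing in
log2 intensity (slope `mnar_strength` per SD of the log2 values, intercept
bisected so the overall missing fraction equals `missing_rate`, default
0.10).  Defaults were picked once as representative of label-free tissue
proteomics; MNAR rather than uniform dropout was chosen because
present-pair denominators and the coverage prefilter must be stressed by
intensity-dependent missingness to mean anything.  All randomness flows
from a single integer seed through one generator, so outputs are
bit-identical across reruns.

What the generator does **not** emulate: peptide-to-protein roll-up,
match-between-runs artifacts, retention-time drift, batch structure,
interfering co-eluting species, or correlated site networks beyond the
planted kinase shifts.  Passing recovery tests therefore demonstrates the
pipeline's statistical behavior under the stated noise model, not
performance on any real cohort.

Validation experiment sizes (chosen to give stable medians while keeping
each experiment in the seconds-to-a-minute range): screen recovery uses 20
seeded cohorts of 1,000 proteins and reports median recall and median
false-discovery proportion; under the default 10 % MNAR dropout roughly a
fifth of planted features fail the pair-coverage prefilter and censoring
attenuates observed effects, so median recall sits near 72 % against an
80 % complete-data target (within the stated ±10 % stochastic tolerance)
with FDR just under 10 %.  KSEA recovery and null calibration use 2,000
sites with a N(0, 0.5) background; the planted kinase (20 substrates,
+1.0 log2) has expected |z| ≈ 9 and ranks first in every run, and null
kinases reach p < 0.05 at ~5 % as the normal approximation predicts.

## Numerical and degenerate-input choices

Zero-variance Welch rows are resolved explicitly (equal means → p = 1,
distinct means → p = 0) instead of propagating 0/0.  A sample with no
present values is an error naming the sample, as is a log2 transform of a
present non-positive value.  KSEA with an all-identical background is a
"degenerate background" error rather than an infinite z.  Ties in the
z-ordering of KSEA results are broken stably (mergesort).  The per-feature
screen denominators never mix subtypes, and features with no present pair
are uncallable rather than zero.

## Known limitations

* The unpaired Welch default discards pairing information in the test
  (the fold-change and concordance criteria retain it); with five pairs
  this costs some power but matches the named method.
* Protein-level phospho aggregation ignores site weighting by intensity
  or localization confidence.
* The kinome-group fixture is illustrative; real analyses should supply a
  full kinase classification table via the `group_map` config path.
* KSEA treats substrate sites as independent; shared peptides or
  correlated sites inflate |z|.
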