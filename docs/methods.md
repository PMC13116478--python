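# Methods

## Essentiality calling and the trichotomy

The unit of input is a gene fitness-effect matrix: cell lines × genes of
real scores (DepMap `CRISPRGeneEffect` CSV dialect, columns labelled
`SYMBOL (ENTREZ)`), where more negative means a larger growth cost of the
knockout and gaps are explicit missing values. A gene is *essential* in a
cell line iff its score is **strictly below** the cutoff (default −1.0, on
the scale where the median pan-essential gene sits near −1); a score of
exactly −1 is non-essential, and a missing score yields a missing call.

Per gene, the essentiality frequency is `n_essential / n_evaluable`, a
proportion over non-missing calls only. Missing scores are excluded from
the denominator — the only convention under which the frequency remains a
proportion of the lines actually evaluated. A gene with no evaluable call
has no frequency; such genes are reported separately, never silently
dropped.

Categories are a pure function of frequency: always essential (AEG)
strictly above 0.90, rarely essential (REG) strictly below 0.10,
partially essential (PEG) the closed interval [0.10, 0.90]. The bounds
are compared as exact rationals — `Fraction(n_essential, n_evaluable)`
against `Fraction(9, 10)` — so boundary cases (1035 of 1150 lines is
exactly 90%) cannot be misclassified by float rounding.

A gene's category is **global**: computed once from its frequency over
all cell lines, then reused by every pathway that contains the gene.
Pathway summaries therefore partition cleanly
(`n_aeg + n_peg + n_reg = n_present`), and deduplicated totals count each
gene once while pathway-level sums count it once per membership; the two
coincide exactly when no categorized gene is shared between pathways.
Pathway genes absent from the matrix are excluded from all denominators
but always listed (`missing_genes`), so discrepancies stay auditable.

## Pathway essentiality fractions

For cell line *c* and pathway *P*, the fraction is the number of
AEG/PEG-category members of *P* called essential in *c*, divided by the
number of *P*'s genes present in the matrix (all categories, REGs
included). Missing calls count as non-essential in the numerator, keeping
fractions comparable across lines with different missingness. The
fraction is bounded by `n_aeg_peg / n_present` and increases by exactly
`1 / n_present` per additional essential AEG/PEG gene.

## Separation detection

Which pathways have "clearly separated" fraction distributions is decided
by a deterministic one-dimensional Otsu rule: sort the pathway's
per-line fractions, find the split maximizing between-group variance
(only splits between distinct values are considered; score ties keep the
first split in sorted order), and define the separation score as
between-group variance over total variance at that split. A pathway is
separated when the score is ≥ `min_score` **and** both groups contain at
least `min_group` (default 5) lines; the selected lines are the upper
group. Constant profiles are never separated.

`min_score` defaults to **0.85**. The best-split variance ratio is not
small for unimodal data — it is exactly 0.75 for a uniform distribution
and ≈ 2/π ≈ 0.64 for a Gaussian — so any threshold below ~0.8 would flag
every pathway. 0.85 sits above the unimodal regime while genuinely
two-regime profiles (including two point masses at any gap, which score
exactly 1) clear it comfortably.

A consequence worth knowing: a pathway whose AEG/PEG members reduce to a
*single* partially-essential gene has a two-point fraction distribution
({0, 1/n_present}) and is flagged whenever both groups are large enough.
This is a real property of the fraction statistic, not an artifact — the
pathways reported as separated in practice are exactly the small
pathways with one partially essential gene — but it means "separated"
should be read as "bimodal fraction profile", not as evidence of a
multi-gene program.

## Cancer-type enrichment

Among the selected (upper-group) lines of a separated pathway, each
cancer type with ≥ 1 annotated line gets
`fraction = n_selected / n_total`; the type is enriched iff the fraction
is **strictly** greater than the threshold (default 0.5 — exactly half is
not enriched). Selected lines absent from the annotation table are
dropped with a warning and reported, never silently counted.

## Synthetic screens

The generator's defaults describe the study conditions the pipeline is
meant for: 1150 cell lines, 12 RCD pathways with sizes
(Apoptosis 134, Autosis 16, Necroptosis 148, Ferroptosis 41,
Autophagy 167, Efferocytosis 156, Mitotic 38, Lysosome-dependent 10,
MPT-driven 16, Immunogenic 28, Parthanatos 20, Pyroptosis 25 — the last
two are placeholders, config-overridable), a gene-set union of 600 unique
genes of which 119 belong to more than one pathway (both hit exactly by
construction: multi-pathway genes are assigned first, to pathway
combinations sampled proportional to remaining capacity, then unique
genes fill the remaining slots), and 20 cancer types of roughly equal
size.

Each gene carries a latent essential-fraction p_g drawn by category —
AEG: U(0.90 + m, 1], PEG: U[0.10 + m, 0.90 − m], REG: U[0, 0.10 − m) —
with category proportions defaulting to 23 : 47 : 549 (the observed
AEG:PEG:REG split over 619 categorized genes). The boundary margin m
defaults to 0.05: at 1150 lines the binomial standard error of a
frequency is ≈ 0.009, so a 0.05 margin puts every gene ≳ 5σ from the
category bounds and finite-sample recovery errors become negligible
(worst-case per-gene misclassification ~1e−14 in separated mode at
n = 1150; still < 1e−3 aggregated at n = 200).

Latent states are Bernoulli(p_g) per (line, gene). Scores come in two
modes: **separated** (essential ~ U[−3.0, −1.1], non-essential ~
U[−0.9, 0.5]; supports strictly straddle −1, so the cutoff call equals
the latent state exactly and correctness bugs cannot hide behind
sampling noise) and **gaussian** (N(−2, 0.25) vs N(0, 0.25); overlapping
tails ~3e−5 past −1, exercising boundary behaviour). Missingness is
uniform at `missing_rate` (default 0).

Three pathways are planted with a block-structured signal by default —
Autosis, Lysosome-dependent cell death and MPT-driven necrosis, the
pathways whose separation the analysis is designed to detect. In each,
one member gene (preferring genes exclusive to that pathway) is essential
with probability `high_p` = 0.9 in the cell lines of a designated block
of cancer types (12, 3 and 2 types respectively) and `low_p` = 0.05
elsewhere; the pathway's remaining members are forced into the
rarely-essential regime, matching the observed structure of separated
pathways (≤ 1 PEG). `low_p` = 0.05 rather than something smaller keeps
the planted gene's marginal frequency safely above the 0.10 REG bound
even for the smallest (2-type, ~10% of lines) block. Ground truth — p_g,
true category, planted flags and the realized latent states — is kept
alongside the matrix, and `recovery_report` compares the pipeline's
output against it, excluding planted genes (whose states are not
exchangeable across lines) and genes within the margin of a bound.

What the generator does **not** emulate: correlated essentiality across
genes (co-essential complexes), cell-line screening-quality batch
effects, copy-number artifacts, score-inference uncertainty, or realistic
cancer-type imbalance. Passing tests therefore demonstrate correctness of
the pipeline's arithmetic and decision rules under the stated mixture
model, not robustness to those real-data phenomena.

## Clustering and plots

Heatmap layouts use hierarchical clustering on both axes (Euclidean
distance, average linkage by default — the common defaults of clustered
heatmap stacks; both configurable). Missing scores are mean-imputed per
gene for distance computation only and never written to any output; a
gene or line with all scores missing is an error naming it. Ties in the
linkage are broken deterministically by lower original index. Every plot
writes a sidecar TSV (the reordered matrix, or the sorted
gene/frequency/category bar data) that is byte-deterministic and serves
as the testable artifact; images are smoke-tested only.

## Determinism and problem sizes

All randomness flows through `numpy.random.default_rng(seed)` (PCG64);
seeds are mandatory, never defaulted, and echoed into the run manifest
together with input hashes and output checksums. Identical (config, seed)
reproduce byte-identical TSV/JSON outputs; the matrix reader parses
floats with numpy's correctly-rounded parser so write→read round-trips
are lossless.

The test suite and `scripts/acceptance.py` run at the full default scale
(600–619 genes × 1150 lines) for the headline quantities, and at reduced
scales (≤ 50 × 20 matrices for the 200-fixture oracle-equivalence sweep;
40–200 lines for unit fixtures) where the property under test does not
depend on size.

## Known limitations

* Pathway membership is matched to matrix columns by exact, case-sensitive
  gene symbol; no alias or history resolution. Unmatched symbols are
  reported, and an ambiguous symbol (two Entrez IDs) is an error.
* The separation rule is a documented operationalization of a visual
  judgement; `min_score` and `min_group` are tunable conventions, and the
  single-PEG discreteness caveat above applies.
* No statistical uncertainty is attached to frequencies or enrichment
  fractions (point estimates only, by design).
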