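# Methods

This note documents the models implemented by `exoantigen`, the defaults of
the synthetic study generator, and the numerical and design choices made
where more than one reasonable option existed. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` themselves compute.

## Selection cascade

Candidate exosome-surface antigens are selected by a cascade of printed
rules applied in order, each logged as a stage with its rule text,
threshold, input count and surviving identifiers. Surviving sets are nested
by construction, so stage counts are non-increasing and the provenance of
every candidate is auditable.

Inequality strictness follows each rule as stated and is covered by
boundary tests: Ig-bound detection is inclusive (counts &ge; 5 in at least
one pool), cell-line detection is strict (counts &gt; 5 in at least 2 of 6
lines), the Ig-bound case/control ratio is inclusive ("1.5 or greater"),
and the 1.25-fold surfaceome and 2.5-fold plasma rules are strict.

Fold changes compare arithmetic means of quantile-normalized counts with no
pseudocount. A protein with positive case mean and zero control mean is
scored `Inf` and passes every fold threshold (it is maximally elevated); a
protein absent from both groups is `undefined` and never passes. A
pseudocount is available as an explicit option and disables the `Inf` path.

"Confirmed expression" is operationalized as FPKM &ge; 1 in at least one of
the profiled cell lines AND tumor RNA-seq log2 normalized count &ge; 1;
both cutoffs are configurable and echoed in reports. Genes missing from the
evidence table fail the stage (no confirmation is available). The count of
external expression datasets reporting tumor overexpression (&ge; 2 of 8)
annotates survivors without filtering them, since such evidence grades
candidates rather than disqualifying the rest.

Exclusion lists: Ig chains are matched by gene-symbol prefix
(IGH/IGK/IGL/IGJ); acute-phase and abundant-plasma proteins ship as
editable newline-delimited text under `exoantigen/data/`. The packaged
lists are curated short versions of widely known annotations, not a
reproduction of any proprietary database.

## Quantile normalization and ties

Every sample column is mapped onto the reference distribution formed by
row-wise means of the column-sorted matrix. On tied data the two desirable
properties — "equal inputs stay equal" and "every column's output multiset
equals the reference exactly" — are mutually exclusive. The default policy
(`ties="stable"`) breaks ties by row order so the exact-multiset contract
holds to machine precision and the map is non-strictly order-preserving
(larger inputs never map below smaller ones; ties may be separated, never
inverted). `ties="mean"` instead assigns each within-column tie block the
mean of the reference values it spans, preserving input equalities at the
cost of the exact-multiset property. Both policies are idempotent.
Normalization is applied per experiment (Ig-bound and cell-line matrices
separately), before any detection or ratio filter.

## Particle normalization

Nanoparticle-tracking tables are long-form per-particle diameters. The
particle count per sample is taken over the closed diameter window
[30, 200] nm — the conventional exosome size window; boundary values count.
MS1 intensities are divided by their sample's in-window count, which cancels
per-sample exosome-yield differences exactly and leaves within-sample ratios
unchanged.

## Statistics

* **Hypergeometric overlap** — inclusive upper tail P(X &ge; k), summed
  from log-pmf terms via log-sum-exp so p-values near 1e-11 and below keep
  full precision. The representation factor k·N/(K·n) is the ratio of
  observed to expected overlap. The genome universe defaults to N = 17,611
  and is overridable per call. Exhaustive-enumeration agreement to 1e-12 is
  asserted for every configuration with N &le; 12.
* **Fisher's exact test** — two-sided by the point-probability criterion
  (all tables at most as probable as observed, conditional on margins).
* **Mann–Whitney** — U from midranks; AUC = U/(n&#8321;n&#8322;). The exact
  null distribution is used when both groups have &le; 8 observations and
  no cross-group ties; otherwise the normal approximation with tie
  correction and no continuity correction. Two groups of identical values
  carry no evidence and return p = 1.
* **Welch t-test** by default; the pooled-variance form is an option. Both
  groups constant with equal means returns p = 1 by convention.
* **BH FDR** — Benjamini–Hochberg step-up, capped at 1 (via statsmodels).
* **Clustering** — complete linkage on 1 − Pearson correlation distances;
  constant rows are rejected by name (their correlation is undefined); ties
  in merge order resolve deterministically from the condensed distance
  matrix order.
* **Annotation-set enrichment** — one hypergeometric test per GMT term,
  BH-adjusted across terms. This is a generic replacement for proprietary
  pathway/localization databases; term content is supplied by the user.

## Serology

Cohort sets measured under different conditions carry location and scale
offsets, so sets are merged by standardizing each antigen within each set
to its healthy controls: subtract the control mean, divide by the control
sample (n−1) standard deviation. At least two controls with non-zero spread
are required per (set, antigen); violations name the offender. The merged
scale makes per-set control means 0 and SDs 1 to machine precision and is
invariant to affine transforms of a whole set.

ROC AUC is trapezoidal with the cases-higher orientation and is asserted
equal to U/(n&#8321;n&#8322;) at 1e-12. Confidence intervals use the DeLong
placement-value variance (a seeded stratified bootstrap is an option);
p-values come from the Mann–Whitney test, two-sided by default with
one-sided available. Multi-antigen runs report BH FDR across antigens.

The bead-assay score is log&#8322;(MFI_exosome / MFI_uncoated). Normalizing
both channels by the anti-Ig bead MFI cancels algebraically in this ratio,
so the anti-Ig-normalized intermediate is reported as a QC column rather
than entering the score — resolving the apparent double specification of
the assay's normalization transparently.

## CDC decoy analysis

Plate assays: percent viability = (experimental / spontaneous) × 100
against the paired antibody-independent (complement-only) well at the same
exosome dose; values may exceed 100; cytotoxicity = 100 − viability.
Total-lysis wells are retained as a QC bound, not used in the estimate.

Live imaging: spontaneous dead-cell counts are subtracted from both the
experimental condition and the no-exosome (serum + complement) control;
negative differences floor at 0; a non-positive control difference is
guarded by &epsilon; = 1e-9 with a warning. The control condition itself
scores 1 by definition. The statistic is invariant to count units as long
as all four inputs share them.

Dose dependence is assessed two ways, both reported: pairwise unpaired
t-tests of each dose against dose 0, and a one-sided permutation test on
the Spearman correlation of dose with per-well cytotoxicity (999
permutations by default, seeded; response midranks are permuted directly,
which is equivalent to permuting responses and re-ranking and lets the
statistic vectorize). Pairwise tests alone do not establish a trend, which
is why the permutation test is primary for dose dependence. A monotonicity
flag marks non-increasing per-dose means.

## Synthetic study generator

The generator emulates the structure, not the content, of a
multi-compartment antigen-discovery study: six cell lines, five
compartments (total cell extract, cell surface, total exosome extract,
exosome surfaceome, exosome cargo), pooled Ig-bound case/control plasma
fractions, six case and six control plasma-exosome samples with
nanoparticle-tracking tables, three serology cohorts, and a
dose-titrated CDC experiment. Ground truth (planted antigen identifiers and
effect sizes) is returned for recovery scoring.

**Count model.** Spectral counts are Gamma-Poisson (negative binomial).
The dispersion parameter is the biological coefficient of variation of the
latent abundance, so the variance is &mu; + (d·&mu;)² and extra-Poisson
noise vanishes proportionally as d &rarr; 0. `nb_dispersion = 0` is the
exact deterministic limit: counts and intensities equal their expectations
(floats), so planted ratios are recovered bit-exactly; for d &gt; 0 counts
are non-negative integers. The d = 0 case is a genuine limit convention —
an arbitrarily small positive d still carries Poisson noise.

**Planted structure.** Planted antigens multiply the surface compartments
(exosome and cell surface) by `surface_fold` (default 2.0) and the case
pools/samples by `case_ratio` (default 3.0); a configurable subset is
additionally absent from control plasma to exercise the `Inf` fold-change
path. Contaminants (Ig chains — case-elevated, as real Ig-bound fractions
are — plus acute-phase/abundant plasma symbols) are planted without surface
enrichment to exercise the exclusion stage, and the canonical marker and
endomembrane panels are planted with 5-fold compartment enrichment so
marker QC has signal to measure. Planted and special proteins sit near the
abundance-scale center (they are by definition the detectable part of a
discovery set); background proteins span a 0.75-log-SD dynamic range.

**Defaults and why.** Baseline mean of 30 counts (the scale of confidently
identified proteins in such screens); 8 case and 8 control Ig-bound pools
(two cohorts contributing several pooled comparisons each); MS1 log-normal
sigma 0.15 (technical-replicate-level CV of particle-normalized label-free
intensities); 1500 tracked particles per sample with diameters
N(110, 16²) nm for plasma and N(82, 3²) nm for cell lines; serology set
sizes (10, 10, 10), (13, 13, 0), (42, 50, 50) for (cases, healthy,
pancreatitis) with distinct location/scale transforms and a 2-SD planted
case effect; CDC baseline cytotoxicity c&#8320; = 40% with
cyto(dose) = c&#8320;/(1 + s·dose), doses 0/1/2.5 µg, 3 replicates, 5%
multiplicative well noise. Raw MS1 intensities scale with each sample's
in-window particle count, so particle normalization removes the yield
factor exactly.

**Determinism.** One master seed; each stage derives a child generator from
the SHA-256 of its stage name, so adding a stage never perturbs the draws
of earlier stages, and equal configurations reproduce bit-identical tables.

**What it does not emulate.** Peptide-level identification and protein
inference, missingness that depends on abundance (dropout), correlated
noise across compartments of the same line, isoform collapsing, batch
structure within a cohort, and real biological pathway structure. Passing
recovery tests on this generator therefore demonstrates that the selection
logic implements its rules correctly with calibrated error rates under the
stated noise model — not that the thresholds would achieve the same
precision/recall on real cohort data.

## Known limitations

* The cascade operates at gene-symbol level; proteoform/isoform resolution
  is out of scope.
* The Ig-bound detection rule is evaluated per pool (any pool); summing
  across pools is a configuration choice, not the default.
* DeLong intervals are asymptotic; with very few samples per class the
  bootstrap option is preferable.
* The permutation trend p-value has resolution 1/(B+1); with the default
  B = 999 the smallest attainable p is 0.001.
* Annotation enrichment treats terms as fixed sets and tests each term
  marginally; no term-overlap correction is attempted.
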