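# Methods

## Hotspot detection

Hotspot candidates are residues carrying at least `min_count = 5` distinct
missense events, where an event is a distinct (sample, alternate amino acid)
pair at a residue — the same substitution reported twice for one sample
counts once. Each candidate is evaluated in windows of 200 and 300 residues
centered on it; both window lengths must satisfy the share criterion
(candidate count ≥ 15% of the window total) for a call. The window lengths
bracket typical protein-domain sizes, so the test asks whether one position
stands out from its own domain-scale neighbourhood; the 15% share is treated
as a plain configuration parameter (its original pathway-enrichment
calibration is out of scope). An overrepresentation mode (candidate count ≥
`overrep_factor` × the window's per-residue expectation) is available as an
alternative to the share criterion.

Numerical choices at the boundaries:

- **Terminal clipping.** The window [c − W/2, c + W/2] is intersected with
  [1, L]; both the share denominator and the Poisson expectation use the
  clipped totals and clipped length, keeping denominators honest for short
  proteins and near termini.
- **The candidate's own events stay in the window total.** This inflates the
  Poisson expectation λ = n_w / W_eff and is therefore conservative.
- **Reported p** is the maximum over window lengths — the least favourable
  window governs.
- **Multiple testing.** Benjamini–Hochberg across all passing candidates of a
  run (all genes pooled), not per gene, since a single joint hotspot list is
  reported.
- Poisson tails come from `scipy.stats.poisson.sf`, clamped into (0, 1].

## Filters

Common-variant exclusion uses a strictly-greater comparison against the 1%
population-frequency threshold, preferring genomic keys and falling back to
(gene, residue) matching when alleles are absent. The deleteriousness filter
keeps a residue when at least one underlying change carries a damaging label
({possibly_damaging, probably_damaging} for PolyPhen-2-style input; the
mapping is configurable). Residues with no prediction at all are flagged
`unscored` and excluded by default — a documented choice, configurable via
`exclude_unscored=False`. Filters flag rather than delete, so they commute
and every call retains its complete flag history.

Annotation transfer from an external sequence source is guarded by a
sequence-agreement check: positional identity ≥ 95% (the source requires
agreement but names no number; 95% is this package's choice) **and** an
identical residue at the hotspot position, which is mandatory regardless of
global identity.

## Tumor-suppressor signatures

Deleterious = nonsense + frameshift indels; the gene is a suppressor
candidate when it has ≥ 25 such events and a deleterious/synonymous ratio
strictly above 0.7. With zero synonymous events and ≥ 25 deleterious ones
the ratio is treated as +∞ and the gene qualifies. Events are deduplicated
per sample exactly as in hotspot counting. Note the count threshold
dominates near the boundary: at a 1.5 rate ratio the rule reaches ~95%
sensitivity only from roughly 70 events per gene, because 40 events put the
expected deleterious count (24) right at the 25-count gate; the recovery
test therefore simulates 100-event genes. "Neutral" genes in that test use
a truncating:synonymous rate ratio of 0.3, the approximate genome-wide
expectation for unselected coding changes.

## Interface extraction and coordinate transfer

Interfaces are dropped wholesale when their complexation significance score
fails the partner-class threshold (strict >, 0.3 protein–protein, 0.05
ligand/nucleic acid); residues burying > 25 Å² within passing interfaces are
interface residues, merged into contiguous segments. Segments shorter than
five residues are padded symmetrically with flanking chain sequence (clipped
at the chain ends) before alignment.

Alignment is Smith–Waterman (BLOSUM62, gap open 10, extend 0.5) via
Biopython's `PairwiseAligner`; a gap of length ℓ costs 10 + 0.5(ℓ − 1)
(the Gotoh convention — the first gap residue carries the opening cost).
Identity is counted over all alignment columns including gaps. A segment
transfers when identity ≥ 80%, or ≥ 60% for alignments longer than ten
columns. Transfer is injective on the target: a segment whose mapped
residues collide with an earlier segment's is recorded as unmapped.

## Interface cluster test

Per protein, each residue contributes a binomial response (samples mutated
at the residue, cohort size minus that) and the model is

    mutated ~ intercept + β_interface·I(interface) + β_disorder·I(disorder)

fitted as a binomial GLM (statsmodels); p is the one-sided likelihood-ratio
tail for β_interface > 0 (half the χ²₁ tail when β̂ > 0, one minus the half
otherwise). The binomial-logistic response construction is this package's
concrete reading of "logistic regression region test" — the original tool's
exact response/offset construction is not printed; a per-residue Poisson
variant was considered and rejected to keep the cohort size as an explicit
denominator. Disorder is consumed as a precomputed binary track (an
upstream 0.5 threshold on short-disorder predictions); predictors are not
recomputed here. Proteins with zero mutations are `untestable` with p = 1.
Under sparse counts the χ² approximation makes the test very slightly
conservative (measured type-I rate ≈ 0.044 at the 0.05 level over repeated
1,000-protein null simulations), which the calibration test tolerates.
Selection across proteins is Benjamini–Hochberg at adjusted p < 0.05, one
test per protein pooling all of its mapped interfaces.

## Cohort analyses

The frequency matrix holds, per hotspot and tumor type (≥ 50 patients;
same-abbreviation cohorts share a label and merge), the fraction of the
type's patients carrying the hotspot mutation. Clustering of tumor types
uses 1 − Pearson correlation between columns (the linkage method is named
in the source only as "median"; correlation distance is the referenced
clustering tool's default and is this package's documented choice) with
median linkage from scipy — height inversions are possible and the Newick
export tolerates them. Bootstrap support resamples hotspot **rows** with
replacement (default 10,000 replicates) and counts the fraction of
replicates whose dendrogram contains the identical leaf set; this is the
plain bootstrap probability — the multiscale/approximately-unbiased
correction of the referenced tool is out of scope. Replicates that produce
a constant column are skipped (contributing no clades), and constant columns
in the input are dropped with a warning.

The heatmap transform keeps rows mutated in ≥ 1/3 of patients in some type,
shows log2 of the percentage (78% → 6.29), and renders zeros one log2 unit
below the smallest positive display value — a concrete reading of "zeros as
the lowest values".

Patient coverage is the fraction of manifest samples with ≥ 1 event in a
gene or (gene, residue) set. Its resampling null draws same-size **gene**
sets (matching the original comparison; a `unit="position"` switch exists)
from genes containing a position with ≥ 5 mutation events, and reports a
normal-tail p against the null mean and SD. Network-neighborhood enrichment
counts distinct labelled first neighbors of the query proteins; its null
keeps each query's degree and redraws that many interactors uniformly from
the non-query nodes. Two-proportion comparisons use χ² with continuity
correction when all expected counts are ≥ 5 and Fisher's exact test
otherwise, with BH adjustment across a batch.

## Synthetic cohorts

`simulate_cohort` draws per-residue background missense events as
Bernoulli(per-residue-per-sample rate) across samples, optionally weighted
up inside an interface mask. A planted hotspot with share *s* receives
round(s/(1−s) · E[background in its window]) extra events in distinct
samples, where the window is the **largest detection window** (300 residues,
clipped) — so the expected share in the smaller window is higher, and a
planted share of 0.10 stays safely below the dual-window 0.15 threshold.
Truncating and synonymous events are Poisson with per-sample gene-wide
rates. All randomness flows from one `numpy.random.default_rng(seed)`;
identical seeds give byte-identical outputs.

What the generator does **not** emulate: trinucleotide-context mutational
signatures, copy-number events, gene-length-correlated background variation,
sample-level mutation-burden heterogeneity, and sequencing artifacts. A
green recovery test therefore establishes that the detector finds planted
concentration of the stated magnitude against a uniform background — not
that it is robust to covariate-structured backgrounds.

The codon-substitution simulation draws an amino acid with equal weight
(default; a codon-equal mode exists — the two descriptions in the source
material disagree and both are implemented), a codon of it uniformly, and
one of its nine single-base changes uniformly. The exact distribution by
enumeration gives P(Glu→Lys) = 1/180 ≈ 0.556% under amino-acid-equal
weighting (2/549 ≈ 0.364% under codon-equal); at 10,000 events the 95%
Monte-Carlo half-width is ≈ 0.15 percentage points, so printed estimates
near 0.6% are statistically indistinguishable from either the analytic
value or a single-run tally. Both denominators (all events,
amino-acid-changing events only) are available.

The uniform null places a stated mutation load uniformly along a
titin-length protein (34,350 aa) and runs the detector per replicate; at
1,000 mutations per replicate the expected number of ≥5-count residues is
~10⁻⁴ per replicate, so 1,000 replicates are expected to be silent.

## Known limitations

- Corpus-scale headline figures (hotspot counts, patient-coverage
  percentages, real tumor-type clusters) require the full pan-cancer corpus
  plus external annotation sources and are not reproduced; the test suite
  replaces them with property-based checks on synthetic data at desk scale.
- Genomic-dialect ingestion handles single-nucleotide substitutions for
  hotspot counting; indels enter only the suppressor signature. Splice-site
  effects, multi-nucleotide phasing and assembly liftover are out of scope.
- The region test's response construction is a documented stand-in (see
  above); absolute p-values from other implementations will differ even
  when rankings agree.
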