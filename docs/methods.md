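# Methods

## Scope and model

`cernet` reimplements, at desk scale, the analysis chain used to study
lncRNA-mediated regulation across three flower developmental stages (McI,
McII, McIII; three biological replicates each).  The package deliberately
consumes *derived* inputs — assembled transcript models, coding-potential
scores, abundance tables, VIP scores — rather than raw reads: read QC,
alignment, transcript assembly, and the internals of coding-potential
scoring and (O)PLS fitting are upstream tools' responsibilities and out of
scope here.  What the package owns is everything those inputs feed:
classification, thresholding, the three direct acting models, and the ceRNA
network rules.

## lncRNA identification

Class codes are assigned per query transcript against the reference by a
fixed precedence (most specific first): `=` exact intron chain; `c`
intron-compatible containment (every query exon inside a reference exon and
the query intron chain a contiguous sub-chain — a query retaining intron
sequence is *not* contained); `j` shared splice junction; `e` single-exon
query overlapping a reference exon and running into the adjacent intron;
`o` other same-strand exonic overlap; `x` opposite-strand exonic overlap;
`i` fully inside one intron; `u` no overlap; `other` anything left (e.g.
same-strand span overlap without exonic overlap).  The reference list is
scanned in input order within each level, so results are deterministic.
Novel transcripts keep codes {u, i, j, x, c, e, o} with exonic length
strictly over 200 nt and strictly more than one exon.  lncRNA calling uses
strict inequalities (CNCI-style score < 0 AND CPC2-style probability < 0.5)
and retains both single-criterion sets for Venn reporting.

Positional classes also use a first-match precedence — intronic → sense →
bidirectional → antisense → intergenic → unclassified — with "promoter"
operationalized as the 1 kb window upstream of the annotated transcription
start (configurable), and "intergenic" requiring flanking protein-coding
genes on both sides; a lncRNA on a gene-free chromosome end is
unclassified.  Both classifiers are checked against independent
base-position-set oracles on randomized mini-genomes.

## Differential stage

Counts are normalized to FPKM (lncRNA, mRNA; library sizes are the column
sums unless supplied) or TPM (miRNA).  The built-in significance engine is
Welch's two-sample t on log2(value + 1); the fold change is
log2((mean_case + 1)/(mean_control + 1)) on the normalized scale.  This is
a deliberate, documented stand-in: the downstream thresholds and set
arithmetic are agnostic to the p-value engine, and a passthrough mode
accepts p-values computed elsewhere.  Degenerate features (zero variance in
both groups) get p = 1 when the means are equal and p = 0 otherwise —
defined limits instead of NaN.  BH adjustment is the standard step-up with
monotonicity enforcement and stable tie handling, verified against a
quadratic-time reference.

Per-layer defaults (boundary-inclusive): lncRNA |log2FC| ≥ 1 with
FDR ≤ 0.05; miRNA |log2FC| ≥ 0.585 with p ≤ 0.05; mRNA |log2FC| ≥ 1 with
p ≤ 0.05; metabolite |log2FC| ≥ 0.585 with a VIP rule.  The VIP rule ships
as VIP ≥ 1, the conventional (O)PLS reading under which VIP ranks
discriminating metabolites; the opposite direction (`vip_direction="le"`)
is selectable and logs a warning, because keeping low-importance
metabolites contradicts that use.  The lncRNA "fold change ≥ 2" rule is
interpreted as linear fold change (log2FC ≥ 1), consistent with the mRNA
rule's explicit log2 form.

## Direct acting models

* **Antisense.**  Hybridization is scored by a local duplex dynamic program
  over antiparallel alignments with a compact, injectable energy table
  (GC −3, AU −2, GU −1 in arbitrary units; +2 per single-nucleotide bulge;
  no intramolecular structure).  The recurrence is
  H(i,j) = e(aᵢ,b′ⱼ) + min{0, H(i−1,j−1), H(i−2,j−1)+β, H(i−1,j−2)+β} on
  the reversed second sequence, with MFE = min(0, min H); traceback ties
  prefer the longer stack, then the smaller indices.  Because the model has
  three parameters it is exhaustively verifiable: the test suite enumerates
  every admissible structure for random short sequence pairs and requires
  exact agreement.  The analysis only thresholds relative energies
  (default cutoff −10 in model units, plus half the shorter of the lncRNA
  and a 50-nt window paired), so a full nearest-neighbor parameter set
  would change numbers but not structure.
* **Cis.**  Any-strand genomic proximity within 10 kb (the field does not
  quantify "neighboring"; the window is configuration-exposed), statistic =
  signed gap, 0 for overlap.
* **Trans.**  Pearson r strictly above 0.999 across the nine samples — an
  extreme cutoff that essentially demands an exact monotone-linear
  relationship; anticorrelated pairs are reported separately, not called.
  Pairs already explained by a cis edge are excluded by default.

## ceRNA rules

MREs are perfect Watson–Crick reverse complements of the miRNA seed
(positions 2–8 from the 5′ end); G:U is disallowed in the seed and N never
pairs or matches.  Candidate members are restricted to differentially
expressed features (union over the three comparisons).  A triad is emitted
iff (a) the miRNA has a site on both the lncRNA and the mRNA; (b) Spearman
ρ(miRNA, lncRNA) ≤ −0.7 and ρ(miRNA, mRNA) ≤ −0.7 with p ≤ 0.05; (c)
ρ(lncRNA, mRNA) ≥ +0.7 with p ≤ 0.05; (d) the shared-miRNA overlap of the
(lncRNA, mRNA) pair is hypergeometrically enriched against the universe of
expressed miRNAs, BH-corrected across all tested pairs, q ≤ 0.05.  The
0.7/0.05 correlation defaults are not dictated by the source analysis;
they were chosen to be stringent at n = 9 (|ρ| = 0.7 has p ≈ 0.036) and
are configuration-exposed.  Spearman uses average ranks with the
t-approximation on n−2 df.  Correlations pool all nine samples; per-stage
means are used only for trend reporting.  Metabolite edges carry no sign
constraint, only significance tiers (*** ≤ 0.001, ** ≤ 0.01, * ≤ 0.05).

## Synthetic data: what is emulated, and what is not

`generate(PlantConfig)` plants, on a two-chromosome toy genome with
three-exon protein-coding genes: lncRNAs in all five positional classes
(placements are solved so the classifier's definition is met exactly);
exact re-assemblies of reference transcripts (class `=`); miRNA seed sites
embedded in sponge lncRNA/mRNA pairs; stage-trend expression with
negative-binomial noise (variance μ + φμ², default φ = 0.05, baseline mean
1000); and metabolites linearly coupled to designated mRNAs.  The genome is
scrubbed of accidental seed-site motifs (both strands) before embedding,
and embedded regions are re-scrubbed for junction artifacts, so the only
MREs are the planted ones.

Three structural facts shape the expression design:

1. *Stage-mean consistency.*  The three pairwise comparisons share the
   three stage means, so log2FC(III vs I) = log2FC(II vs I) +
   log2FC(III vs II) holds exactly for planted effects.  Membership and
   direction patterns must respect this identity (e.g. a feature DE in
   II-vs-I and III-vs-I only must have the same sign in both).
2. *Normalization neutrality.*  FPKM/TPM divide by per-sample totals, so
   the expected column sum must be stage-invariant or normalization itself
   shifts every fold change.  Each layer therefore carries two "ballast"
   subgroups whose shared stage patterns are solved in closed form to
   equalize the expected totals.
3. *Margin discipline.*  With three replicates the Welch variance estimate
   has two df per group and occasionally triples; planted per-comparison
   effects are kept at ≥ 2× the configured effect (trend steps of 2E,
   default E = 3) and ballast patterns are required to sit at least 2 log2
   units beyond every cutoff, so threshold recovery is statistically
   deterministic rather than merely likely.  No feature is ever planted
   near a threshold.

Decoy chains (200 by default around 10 planted triads) fail one rule each
*deterministically*: shared-site miRNAs planted positively coupled to the
pair (negative-correlation rule fails), site-on-lncRNA-only miRNAs (no
candidate pair forms), and anticorrelated lncRNA/mRNA pairs with shared
sites (positive-correlation rule fails).  Planting decoys as merely
"uncorrelated" would make perfect precision a coin flip across seeds.

The calibrated fixture (`paper_fixture`) scales the lncRNA layer to 3,955
called lncRNAs among 7,620 scored transcripts and plants per-comparison DE
memberships realizing the study-scale cardinalities: |A| = 418, |B| = 1154,
|C| = 880 split 190/228, 552/602, 426/454 up/down, with exclusive Venn
regions (65, 421, 127, 133, 153, 533, 67) — pairwise overlaps AB = 200,
AC = 220, BC = 600, chosen feasible and frozen; inclusion–exclusion gives
the union 1,499 and common set 67.  Single-comparison members use ±4/3 /
∓2/3 stage patterns (the widest margins the shared stage means allow
around the FC-2 cutoff, ±1/3 log2 on each side); multi-comparison members
use ±2 or ±1.5/3 patterns; null features absorb the per-stage count
imbalance (their implied |log2FC| stays ≈ 0.1).  The fixture uses
dispersion 0.002 and baseline mean 10,000 — deeply sequenced, low-noise
features — so the ±1/3 margins are ≈ 6σ and the recovered counts are
identical for every seed; the seed drives only the count noise.  Score
strata are drawn with wide gaps around the two coding-potential cutoffs.

What the generator does **not** emulate: realistic sequence composition,
read-level artifacts, transcript-assembly errors, dispersion–mean trends,
correlated replicate structure, imperfect or G:U-containing miRNA sites,
and metabolite matrix effects.  Passing tests therefore demonstrate that
the pipeline's logic recovers planted structure exactly under its own
model assumptions — not that the thresholds are optimal for real data.

## Numerical choices

* Internal coordinates are 0-based half-open; GTF/GFF3 conversion happens
  only at the I/O boundary.  Strand "." is rejected for exons (strand is
  semantically required by the classifiers).
* TSV is the only tabular dialect; network and Sankey tables are sorted on
  every column, so output is a pure function of the edge multiset.
* Pseudocount 1 on the normalized scale for all fold changes
  (configurable).
* Zero-variance vectors: Spearman returns (NaN, p = 1) with a warning;
  trans correlation skips the feature with a logged count.
* Hypergeometric tails and Welch's t come from scipy; both are verified
  against brute-force references (pmf summation; closed forms) in tests.

## Problem sizes

The default validation bundle uses 40 protein-coding genes, 60 lncRNAs
(20 class-planted, 40 expression roles), 30 miRNAs, 10 triads among 200
decoys; the fixture scales only the lncRNA/score layers (3,955 / 7,620
rows).  The type-I-error check uses 1,000 null features across 50 seeds.
These sizes keep the full validation suite under a minute per stage while
leaving every statistical margin analysis (above) intact.

## Known limitations

* The duplex model is a three-parameter stacking-free approximation; its
  energies are not thermodynamic kcal/mol and only relative comparisons
  are meaningful.
* The Welch stand-in is anticonservative for very low counts compared with
  negative-binomial engines; for real count data, supply external p-values
  via passthrough mode.
* MRE detection is seed-only (7-mer, no G:U, no supplementary pairing);
  an optional duplex-energy refinement of each site is available but no
  free-energy cutoff is imposed by default.
* qPCR concordance uses OLS (not Deming) regression, matching the simple
  fit conventionally reported; replicate Ct values are averaged per
  (feature, sample) before ΔCt.
* The printed slope/R reference pairs for qPCR concordance depend on
  unpublished raw Ct values and serve as format references only; the
  implementation is validated against closed-form OLS instead.
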