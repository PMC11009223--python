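# Methods

## Data model

The unit of analysis is the ASV — an exact denoised 16S V3–V4 amplicon
sequence, used as a strain-level proxy. ASV identity is plain string
equality on the identifier (the sequence itself, or a stable hash when a
table ships hashes), which is what makes cross-farm and cross-file
comparisons meaningful without any re-clustering. Three tables describe a
study: a sample × ASV count matrix (`FeatureTable`, QIIME2-export TSV with
a `#OTU ID` header; a transposed dialect is supported behind a flag), a
taxonomy map (Greengenes 13.8-style `k__…;p__…;…;s__…` lineages, with
square-bracketed contested names such as `[Weeksellaceae]` preserved
verbatim) and per-sample metadata (animal, farm, body site, nasal depth
site, molecule, control flag). Metadata vocabularies are closed sets:
unknown levels are errors, not new categories, because silent factor typos
corrupt every stratified analysis downstream. Taxonomy lookups for unknown
ASVs fail loudly rather than defaulting to "Unassigned".

## Filtering

Contaminant removal follows the blank-subtraction rule: any ASV with a
nonzero count in a negative-control library is removed, separately per
nucleic-acid type (DNA blanks clean DNA libraries, RNA blanks RNA
libraries), since the two library preparations have distinct reagent
contamination profiles. The detection threshold is count ≥ 1 by design —
no frequency/prevalence model — so the filter is exact and idempotent.
When one table mixes both molecules, flagged cells are zeroed per
molecule and a column is dropped outright only when it is flagged for
every molecule present; on single-molecule tables (the common case, and
the simulator's native output) this reduces to removing the column.
Organelle filtering removes kingdom Archaea, class Chloroplast and family
mitochondria, matched case-insensitively with brackets ignored for this
test only. Both filters only delete rows/columns; surviving counts are
never edited.

## Composition

Relative abundance is count over sample depth; zero-depth samples are a
hard error at construction, so off-simplex rows cannot slip through.
Aggregation at a rank groups ASVs by the full lineage prefix down to that
rank and then merges groups that share a display label; taxa unnamed at
the rank are shown as `<deepest named ancestor> (unclass.)`. Aggregation
conserves per-sample totals to 1e-9.

The gut-associated fraction is the summed relative abundance of
*Bacteroidales* and *Clostridiales*, matched by string equality on the
`o__` slot against Greengenes 13.8 names (no synonym mapping — aliasing
e.g. Eubacteriales would silently change the estimand). "Mean relative
abundance across samples" is always the unweighted arithmetic mean over
the samples in the summarized set, zeros included. Reported SDs are
sample SDs (ddof = 1), and output headers say so. The order summary
partitions each sample into gut orders (always reported separately,
whatever their mean), "Other" (non-gut orders whose *mean* abundance
across the summarized samples exceeds the display threshold, default 1%)
and "Low abundant" (the rest); the four parts sum to 1 by construction.

The alternative gut definition is a core-microbiome criterion: aggregate
a reference gut cohort at a rank (default genus) and keep taxa detected
above a detection threshold (default 0: presence) in at least a
prevalence threshold (default 0.5) of reference samples. The defaults are
deliberately conservative and fully configurable, and the result records
the thresholds that produced it. Both thresholds are monotone: lowering
either can only grow the set.

## Overlap

For one farm, one body site, one molecule (DNA by default — the survey
design sequences DNA everywhere and RNA in a subset), ASVs of a taxon
group (an order, n = 100 by convention for the gut orders; or a
nasal-colonizer family, n = 20) are ranked by mean relative abundance
across the stratum's animals, zeros included, ties broken by ascending
ASV id so the ranking is deterministic. The shared percentage of the two
top-N lists is reported under two conventions, both exposed because
published figures rarely state which is in use: |shared|/|union|
(default) and |shared|/N. The union convention is never larger. ASVs
present in the shared set of at least `min_farms` farms (default: all)
form the cross-farm shared set.

## Activity

DNA and RNA samples are paired on (animal, body site, nasal site);
unpaired samples are reported and excluded. Two estimators are produced
and labeled, because they answer different questions:

* **ratio of means** (`taxon_activity`): mean RNA abundance across
  matched animals over mean DNA abundance, per taxon. No pseudocount; a
  taxon with zero mean DNA abundance keeps its record with an undefined
  ratio.
* **mean of per-animal ratios** (`per_animal_family_ratios` →
  `compare_ratio_distributions`): per animal,
  (rel_RNA + ε)/(rel_DNA + ε) with ε defaulting to half the smallest
  nonzero relative abundance in the combined matched tables — a
  deterministic, scale-aware zero handling, recorded in the output
  metadata. Each gut family's per-animal ratio distribution is compared
  against the pooled ratios of the reference nasal-colonizer families
  (*Lactobacillaceae*, *Moraxellaceae*, *Pasteurellaceae*,
  *Streptococcaceae*, *[Weeksellaceae]*) with a two-sided Mann–Whitney U
  test, Benjamini–Hochberg adjusted across families at 0.05. The rank
  test is a robustness choice for heavy-tailed compositional ratios, and
  is pluggable (Brunner–Munzel is provided); families with fewer than 3
  usable animals are excluded with a warning.

A point worth stating explicitly: relative abundances are compositional,
so if one taxon's transcription is up-weighted by a factor *a*, its
measured RNA/DNA ratio is *a* / Σⱼ aⱼ pⱼ, not *a* — boosting one taxon
necessarily dilutes all others. Ratios therefore recover activity factors
directly only when the reweighted taxa are minor community members, and
are otherwise interpretable relative to one another. The simulator's
truth ledger exposes the closed-composition expectation
(`expected_activity_ratio`) so recovery tests can target the estimator's
actual estimand.

## Simulator

The generator emulates a multi-farm paired-site amplicon survey:

* per farm, a pool of ASVs (uniform random 250-nt sequences, so identity
  is exact-string semantics as in real data) split into shared,
  nasal-only and rectal-only subsets; taxonomy cells are apportioned by
  largest remainder and shuffled across the pool;
* one log-normal(μ = 0, σ = 1.5) base weight per pool ASV, so a shared
  ASV keeps consistent cross-site ranks; per site the weights over that
  site's pool are normalized to base proportions;
* per animal, proportions ~ Dirichlet(α₀ · base) with α₀ = 50 (visible
  animal-to-animal variation at roughly the level seen in piglet swab
  surveys), then counts ~ multinomial at a log-normal depth (median
  5×10⁴ reads, CV 0.3 — a typical MiSeq per-sample yield);
* RNA libraries reweight each animal's proportions by the per-family
  activity factor before multinomial sampling, sharing the animal's
  Dirichlet draw with the DNA library (the two libraries come from the
  same swab);
* one blank per molecule containing only that molecule's contaminants
  (defaults 21 DNA / 41 RNA), counts Poisson(λ = 5) conditioned ≥ 1 so
  every planted contaminant is detectable; contaminants live in a
  disjoint ASV namespace unless a leak fraction is set;
* randomness is organized into per-component substreams
  (cross-farm pool, farm pools, each animal, controls) derived from one
  root seed, so the same seed is bit-reproducible and adding animals
  does not perturb pool draws.

Planting controls exist for recovery tests: `target_order_fractions` /
`target_family_fractions` rescale base proportions so chosen groups hit
exact community shares in every farm and site; `plant_shared_on_top`
assigns the largest base weights to the shared subset and
`shared_abundance_boost` multiplies them, guaranteeing the shared pool is
the top-k of both sites with a known abundance gap. The truth ledger
stores pools, lineages, per-site base abundances, expected order
fractions, activity factors and contaminant ids, and `expected_overlap`
re-applies the exact top-N rule to the noiseless base abundances to give
the recovery target.

What the simulator does **not** model: sequencing error and chimeras
(ASV tables are taken as already denoised), PCR/primer bias, phylogenetic
correlation between related ASVs, overdispersion beyond the Dirichlet,
and real ecological covariance between taxa. Passing recovery tests
therefore shows the estimators are correct for the stated sampling model,
not that real swab data meet that model.

## Validation design and problem sizes

The test-suite recovery scenarios use 3 farms × 8 animals per site
(matching the reference cohort design of 24 animals), depth 5×10⁴–10⁵,
and a single fixed seed; the null false-positive check uses 20
replicate seeds. Overlap recovery plants the shared pool as the top-k
with a 3× gap at sharing levels {0, 25, 50, 100}% of N = 20 (20
site-only fillers, none for the fully-shared case, so every planted level
is identifiable from the rank structure); estimates must land within ±10
percentage points of `expected_overlap`. Gut-fraction recovery plants
10% / 20% order shares and requires ±2 points on the recovered means.
Activity recovery plants factors {0.25, 1, 3} on three families pinned at
5–10% community shares (see the compositional note above) and requires
±20% relative error; the all-factors-1 null must flag ≤ 10% of families
at BH 0.05. These sizes keep the whole suite in a few seconds on one
core while leaving the pass margins dominated by the estimators, not the
noise floor.

## Numerical choices and edge cases

Simplex membership is checked to 1e-9 (relative-abundance rows, order
summaries, aggregation conservation). Sorting tie-breaks are always
(metric desc, label asc) so every ranking is total and deterministic.
Empty strata, empty taxon groups, zero-depth samples, missing taxonomy
entries and controls missing from tables are hard errors; an empty
prevalence-based gut set is a warning (strict thresholds are a legitimate
choice). `FeatureTable` accepts float-typed input only when every value
is integral. Dirichlet draws with very small concentration parameters can
underflow to exact zeros; this is harmless (zero proportions are valid
multinomial inputs) and mirrors genuinely absent taxa.

## Known limitations

* Order/family name matching is exact Greengenes 13.8 vocabulary; tables
  classified against SILVA/GTDB nomenclature need relabeling first.
* The per-molecule contaminant filter assumes blanks are labeled with the
  molecule they control for; unlabeled blanks cannot be assigned.
* `shared_pct` conventions differ whenever top-N lists differ in
  content; comparisons across studies must fix the denominator.
* The ratio tests compare each family against pooled colonizer families;
  with few animals the pooled reference dominates the ranks and power is
  limited.
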