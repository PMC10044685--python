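# Methods

## Distance model

Pairwise comparisons use pairwise deletion: any alignment column in which
either sequence shows a gap, an `N`, or an IUPAC ambiguity code is dropped
from that pair only. Ambiguity codes are excluded rather than fractionally
matched so that every count is an integer and every run deterministic.
Over the `n` retained columns, `P` is the proportion of transition
differences (purine–purine or pyrimidine–pyrimidine) and `Q` of
transversions. The Kimura two-parameter distance

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))

corrects for multiple hits under unequal transition/transversion rates;
it is undefined (a saturation error, never silently clamped) when
`1 - 2P - Q <= 0` or `1 - 2Q <= 0`. The p-distance is `P + Q`. For every
comparable pair `d >= p`, with equality only at `p = 0`. Distances are
stored as proportions; reports render them as percentages with two
decimals. No rate-heterogeneity (gamma) correction and no other
substitution models are provided.

Sequences are treated as already aligned to the same locus window (the
~654 bp CO1 barcode fragment); there is no re-alignment stage. Equal
length is required for distance computation; the identity search accepts
near-equal lengths via end-gap-free alignment (below).

## Tree construction

Neighbor joining follows the Saitou–Nei agglomeration on the Q criterion.
Two choices make it fully deterministic and well behaved:

* ties in the Q criterion are broken toward the lexicographically
  smallest pair of subtree labels (the smallest leaf name within each
  active subtree);
* a negative branch-length estimate is clamped to zero and its deficit
  transferred to the sibling branch, preserving the pair's summed length;
  each clamp is logged.

On an additive input matrix the reconstructed leaf-to-leaf path lengths
reproduce the matrix to floating-point precision; the test suite checks
this against random additive matrices and against scikit-bio's
implementation as an independent oracle. Trees are held as scikit-bio
`TreeNode` objects; midpoint rooting (the only rooting offered) places the
root halfway along the longest leaf-to-leaf path, leaving the two deepest
leaves equidistant from the root.

Bootstrap supports resample alignment columns with replacement, rebuild
the distance matrix and NJ tree per replicate, and report for each
internal edge the percentage of completed replicates containing the same
leaf bipartition. Replicates in which any pair saturates are skipped with
a warning and excluded from the denominator. Tests run 25–100 replicates;
the command-line default is 1000.

## Identification

**Database approach.** Each query is ranked against the local reference
library by percent identity. Equal-length pairs are compared column by
column under pairwise deletion; unequal lengths go through an end-gap-free
global alignment in which terminal-gap columns are excluded and internal
gaps count as differences. An optional orientation check also scores the
reverse complement. One flag summarizes each query:

| flag | condition (evaluated in this order) |
|------|--------------------------------------|
| LS | top identity below the strong threshold (default 99.0%; a match at exactly 99.0x% counts as strong) |
| MU | best-matching reference label indeterminate ("sp." or "cf." form) |
| MM | a second species within 0.5 percentage points of the top identity |
| DS | top species differs from the field identification |
| OK | otherwise |

The multi-species window (0.5 points) is a package default — remote
search engines do not document an equivalent — and is configurable.
Query cover is not used in flagging.

**Tree approach.** Walking rootward from the query leaf of the
midpoint-rooted NJ tree, the first clade containing reference material
determines the candidate species. If its references are a single species
and the query's nearest-reference K2P distance is at most 2%
(`t_conspecific`), the query is assigned to that species; up to 5%
(`t_cryptic`) it is assigned with a `cryptic_split` mark, signalling a
deep intraspecific divergence worth taxonomic follow-up; beyond that, or
when the clade mixes species, no tree assignment is made. The 2%/5%
defaults bracket the conspecific (0.2–1.3%), cryptic (3.7–3.8%) and
distinct-lineage (5.2%) distances observed in elasmobranch CO1 surveys.

**Consensus.** Agreement of both approaches verifies the field
identification. A strong different-species match corroborated by the tree
reassigns the sample. Low-similarity queries keep the field name when no
conspecific reference exists (nothing to compare against) and otherwise
become "cf."-qualified working names. Multi-species ties resolved by the
tree are verified with a cautionary note (misdeposited reference
sequences are common); unresolved ones retain the field name. Reference
curation is declarative: rename overrides correct deposited labels before
matching, and retain overrides let morphology outrank a conflicting
database match. `RETAINED` and `INCONCLUSIVE` statuses both count as
inconclusive identifications in summaries.

**Tabulated mode.** When only a printed verification table is available
(best match, percent, marker, tree match, consensus per sample), flags
are recomputed from the printed columns: low similarity from the
percentage, different-species from the name columns, and the
multi-species/uncertain conditions from the row's annotation marker,
since printed tables do not carry full hit lists. An `R` marker (revised
reference identity) means the printed best match already carries the
corrected label and is not a conflict.

## Inter-rank categories and statistics

Each unordered pair of individuals contributes one distance to the
category named by the most specific rank at which the two lineages
differ: intraspecific, interspecific, inter-genus, inter-subfamily,
inter-family, inter-order, inter-infraclass, inter-class. Category counts
always sum to `n(n-1)/2`. A missing subfamily equals the family, so the
inter-subfamily category only arises where a subfamilial classification
exists (in the packaged taxonomy, only within Dasyatidae — the whipray
subfamilies Dasyatinae, Neotrygoninae, Urogymninae, Hypolophinae).
p-distance is the default metric for category summaries; K2P is
switchable.

One-way fixed-effects ANOVA (via `scipy.stats.f_oneway`) compares the
categories, supplemented by Tukey's HSD with
`q = |mean_i - mean_j| / sqrt(MS_within (1/n_i + 1/n_j) / 2)` and
p-values from the studentized-range distribution. Distance pairs share
individuals, so the independence assumption of both tests is violated;
they are reported as is customary in barcoding-gap analyses, without
correction, and should be read descriptively. No Welch correction is
applied by default.

## Packaged fixtures

`data/sample_table.tsv` is a transcription of the per-sample verification
table of a 175-individual Malaysian shark-and-batoid CO1 survey, with one
normalized dialect: abbreviated genus names are expanded, annotation
markers ({DS, LS, MM, MU, R}) live in their own column, and the
inconclusive superscript is a separate boolean column. The
secondary-database (BOLD) match columns are kept as printed, typos
included, and are not used in flag recomputation. Three low-similarity
rows (88.01%) carry no printed marker; the low-similarity cohort is
therefore always recomputed from the percentages, which also matches the
survey's stated cohort of 15.

`data/taxonomy.tsv` assigns every species name appearing in the table
(field, best-match, tree and consensus columns) its rank chain under a
single scheme chosen at packaging time: Galeocerdo remains in
Carcharhinidae and Aetobatus in Myliobatidae, giving the survey's 20
families; subfamilies are recorded only for Dasyatidae. Sharks carry
infraclass Selachii, batoids Batoidea; the chimaera outgroup is
Holocephali with no infraclass.

## Synthetic studies

The generator builds a balanced ultrametric taxonomy (two infraclasses ×
orders × families × genera × species, plus one chimaera-like outgroup
species in a second class) in which any two individuals' path length
equals the target divergence of the most specific rank separating them.
Defaults: intraspecific 0.5%, interspecific 5%, inter-genus 10%,
inter-family 15%, inter-order 20%, inter-infraclass 25%, inter-class 30%
(K2P scale), 654 bp, transition/transversion rate ratio kappa = 4, three
samples and two references per species — two references mirroring common
reference-library practice of depositing one or two sequences per
species. Sequences evolve by the exact two-parameter transition
probabilities per branch, so the K2P estimator is unbiased for path
length. No indels, codon structure, selection, or among-site rate
variation are simulated; gap handling is exercised by hand-built fixtures
instead.

Planted events, with defaults chosen to give a handful of each per study
(misidentified 5% of samples; novel, cryptic and ambiguous 6% of species
each):

* *misidentified* — the reported species is swapped for another species
  that has references;
* *novel* — a species' references are withheld entirely, so its samples
  can only match congeners (expected identity ≈ 95%);
* *cryptic* — one sample is replaced by a divergent conspecific
  haplotype derived from a reference by exact transition/transversion
  substitution counts at a target K2P distance drawn from 3.6–4.4%, so
  the realized divergence stays inside the 3.5–5% deep-split window
  rather than being left to substitution noise;
* *ambiguous* — a pseudo-sister species deposits a reference inside the
  focal species' clade, so database matches tie across two labels.

What passing tests on this generator do show: the flag rules, tree
assignment, and consensus logic recover planted events at high rates
under the generative model the distance estimators assume. What they do
not show: robustness to alignment error, indels, heterogeneous rates,
contamination, or database label noise beyond the planted kinds — real
surveys face all of these.

## Problem sizes and numerical choices

Tests and the acceptance script use scaled-down but structurally complete
problems: 32-species studies (98 queries, ~66 references), 50 seeded
replicates for event-recovery rates, and 100 bootstrap replicates at 40
taxa — sizes at which every stage's invariants are checkable in seconds.
NJ additivity and midpoint balance are asserted to 1e-9; the K2P closed
form to 1e-9; Tukey p-values against the studentized-range distribution
to 1e-6. Seeds are explicit arguments throughout; no global random state
is used.

## Known limitations

* The identity search is exhaustive against the library (no k-mer
  prefilter); adequate for curated libraries of hundreds of references,
  not for database-scale search.
* Remote-database percent identities are not reproducible offline (they
  depend on database versions); the tabulated mode exists precisely to
  work from a printed record.
* ANOVA/Tukey on shared-individual distance pairs is descriptive, not
  inferential (see above).
* Maximum-likelihood topology search and model selection are out of
  scope; the tree stage is distance-based NJ on K2P, which reproduces
  clade-plus-distance reasoning but not likelihood supports.
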