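# Methods

## Scope and model

`rflpkit` models the dry-lab half of a PCR-RFLP species-identification
assay: given marker sequences (mitochondrial 16S rRNA or COI amplicons), it
predicts what a thermocycler, a restriction enzyme, and a 4% agarose gel
would show, and operates on those predictions — grouping patterns,
constructing identification keys, and screening enzymes. Wet-lab steps (DNA
extraction, amplification chemistry, gel casting) and sequence curation
(database searches, alignment, tree building) are out of scope; standard
tooling exists for all of them.

## IUPAC matching semantics

Every matching operation distinguishes two modes over the 15-letter
ambiguity alphabet:

* **strict** — the template symbol's base set must be a *subset* of the
  pattern symbol's: the match holds no matter which concrete base the
  ambiguous template position stands for. `R` in a primer matches template
  `A`, but a template `N` matches nothing smaller than `N` in the pattern.
* **permissive** — the base sets need only intersect: the match is
  *possible*.

Digestion defaults to strict so predicted patterns are reproducible — an
ambiguous base in a deposited sequence only yields a predicted cut when the
cut is guaranteed. Permissive mode is exposed for exploratory screening and
always produces a superset of the strict cut set.

## In-silico PCR

Primers are degenerate 5′→3′ oligos; a reverse primer's binding site is
searched as its reverse complement on the plus strand. Matching allows a
whole-primer mismatch budget (default 2) but requires the three 3′-terminal
primer positions to match exactly, reflecting polymerase intolerance of 3′
mispairing. Products pair a forward hit with a downstream reverse hit,
include both primer regions (PCR products are digested untrimmed;
`trim_primers` removes them because database sequences may lack primer
regions), and are capped at 2,000 bp to suppress spurious distant pairings.
Coordinates are 0-based half-open on the plus strand; on circular templates
an origin-spanning product reports `end > len(template)`, interpreted
modulo the length. A template with no valid pairing returns an empty list,
not an error — real templates genuinely fail to amplify with some pairs,
as COI primers often do for some tick species.

## Digestion

An enzyme is (name, IUPAC site, top-strand cut offset); DraI is
`TTTAAA`/3, AluI `AGCT`/2. Only fragment lengths are observable on an
agarose gel, so a single blunt-cut coordinate suffices and sticky-end
geometry is ignored. Both strands are searched: a non-palindromic site
occurring as its reverse complement at position *i* cuts at
*i* + |site| − offset. Overlapping occurrences all count; duplicate cut
coordinates collapse; cuts at the molecule ends produce no fragment.
Fragments are consecutive differences of the cut list bounded by 0 and the
amplicon length, so they always sum to the length. Site search is
implemented as compiled character-class regexes with lookahead (one pass
per strand); the test bench checks it against a naive positionwise re-scan
oracle and against Bio.Restriction on concrete sequences.

## Gel model

Two integer knobs emulate a 4% agarose gel, both recorded in every output:

* `min_visible` (default 40 bp) — smaller fragments run off or stain too
  faintly to call;
* `co_migration_tol` (default 5 bp) — fragments closer than this appear as
  one band and band sizes closer than this compare equal.

Visibility is applied first; then co-migrating fragments are merged by
single linkage into one band at the rounded mean (a single indistinguishable
band is what the gel shows). Both defaults are judgement calls for a 4% gel
read by eye; published pattern comparisons were visual and give no numeric
tolerance, so the knobs are configuration, not constants.

Tolerance-based band equality is reflexive and symmetric but **not
transitive** (100≈104≈108 but 100≉108). Pattern grouping therefore uses
leader clustering in input (file) order: a digest joins the first
catalogued pattern it equals, else founds a new one. This makes catalogues
reproducible and order-stable at the cost of a mild dependence on input
order, which exact partitioning cannot avoid under a non-transitive
relation.

## Dichotomous keys

A key is an ordered list of couplets; each couplet's two leads are
predicates over the visible band list: band-count thresholds, size
thresholds on the nth-largest band, and approximate-size predicates
("band 2 within tolerance of 200 bp"). "Top"/"largest" map to rank 1 and
"middle" to rank 2 of the descending band list — consistent with the
three-band couplets of the published key, and stated explicitly because
"middle" is undefined for larger patterns.

`build_key` splits the catalogue's distinct patterns greedily: candidate
features are band-count thresholds at observed counts, nth-band thresholds
at midpoints of adjacent observed values whose gap exceeds twice the
co-migration tolerance, and has-band-near features at observed values; the
feature maximising the smaller branch wins, with deterministic tie-breaks
(band-count kind first, then smaller rank, then larger threshold margin).
Couplets are numbered breadth-first with back-references. Two species
sharing a pattern abort construction with an explicit
`IndistinguishableSpecies` error — the published 16S assay has exactly this
property for *H. longicornis* vs *H. asiatica*, which is a finding, not a
bug. The midpoint-with-margin rule makes classifications stable under band
reads off by up to one tolerance unit whenever the training gaps were wide
enough.

`apply_key` first passes the observed bands through the key's gel model,
then walks the couplets, returning the species plus the visited couplet
trace, near-threshold ambiguity warnings, or `undetermined` with the
stalling couplet when no lead holds. The published key's couplet 3 leaves
two-band patterns with a largest band between 300 and 400 bp unclassified;
the package deliberately returns `undetermined` there rather than inventing
a boundary the key does not state.

Keys serialise two ways: a canonical one-couplet-per-line machine format
(the on-disk form, with a `# key=… enzyme=… tol=…` header) and a
paper-style pretty print with dot leaders. Both parse back to an identical
key. The published North-American key ships as `na16s` (five couplets,
thresholds 200/400/300/200/175/160 bp) and works without any sequence data.

## Enzyme screening

For each library enzyme, all amplicons are digested and catalogued; a
species pair is *separated* iff no pattern of one equals any pattern of the
other under the gel model. The score is the separated fraction of species
pairs — the simplest formalisation of "find candidate enzymes". Species
with multiple patterns are tolerated (real COI data shows them) but counted
as a tie-break penalty; remaining ties prefer fewer total cuts (simpler
gels) and finally name, making rankings deterministic. A target-species
mode reports whether one focal species (e.g. the invasive one) separates
from every other. Scores are computed per enzyme independently, so library
composition never changes an enzyme's score.

## Synthetic data generator

The generator emulates a curated, species-labelled amplicon set: per
species (and per planted pattern) it builds a master amplicon with a
concrete realisation of the forward primer at the 5′ end, the reverse
primer's reverse complement at the 3′ end, concrete enzyme sites exactly at
the planted cut positions, and the site excluded everywhere else by
rejection sampling; per-sequence substitutions/indels are then applied
outside the protected windows (primers + sites). Defaults mirror the 16S
assay geometry: 438 bp amplicons, DraI, 10 sequences per species. With
`shared_background=True` all species are stamped onto one common
background, so species differ *only* inside planted site windows — the
right null model for enzyme-screening experiments, where independent
backgrounds would let every frequent cutter discriminate trivially.

Planted fragment lists are exact ground truth at zero mutation rate.
At positive rates, mutations may *create* new sites (planted ones are
protected), adding patterns; the truth table logs per-sequence mutation
counts so such events are attributable. Pattern-count recovery under noise
is accordingly measured per species: at a 1% per-site rate, roughly one
dataset in six gains a spurious DraI site somewhere among 30 sequences,
while over 90% of individual species keep their planted count.

`random_discriminable_config` draws catalogues whose planted patterns are
pairwise robustly distinct *after* the gel model (band-count difference or
a positional gap exceeding twice the tolerance plus 2 bp), by rejection
sampling fragments from a coarse grid. This is what makes exact-recovery
and key-self-consistency experiments meaningful rather than fragile.

What the generator does **not** emulate: realistic mitochondrial base
composition, phylogenetic correlation between species, alignment gaps, or
sequencing error. Passing tests show the machinery is correct on its own
terms, not that any particular real species pair is separable — that
always depends on the actual sequences fed in.

## Numerical and degenerate-input choices

* Band merging uses floor(mean + 0.5) — deterministic half-up rounding,
  avoiding banker's rounding surprises in band sizes.
* All-invisible digests raise `EmptyPattern` rather than returning an empty
  band list; empty FASTA input raises `EmptyInput`.
* `U` is normalised to `T`; gap characters are rejected (the toolkit works
  on unaligned amplicons).
* Primer/site validation failures name the record and 0-based position.
* Sequence ids must be unique per file; species labels come from bracketed
  header tags (`[species=…]`) or a two-column sidecar map, header tags
  winning.
* All randomness flows through seeded `numpy` generators; identical
  configurations produce byte-identical FASTA.

## Problem sizes used in verification

The test bench and `scripts/acceptance.py` use desk-scale sizes chosen to
exercise every code path while staying quick: 1,000 random 500-nt sequences
× 7 enzymes for the digestion oracle; 50 random configurations for exact
recovery; 100 seeded screening datasets (3 species × 20 sequences, ≤ 2
background substitutions each) for planted-enzyme ranking; 200 random
catalogues for key self-consistency. Published-key checks use the band
patterns printed with the key itself.

## Known limitations

* Partial digestion, star activity and methylation sensitivity are not
  modelled; patterns assume complete digestion.
* Band intensity (fragment molarity/staining) is ignored; only presence and
  size matter.
* The key builder's feature pool cannot express conjunctions; catalogues
  requiring them fail construction explicitly rather than silently.
* Multi-enzyme (double-digest) screening is out of scope.
* The bundled 42-enzyme library is a commercial subset, not REBASE.
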