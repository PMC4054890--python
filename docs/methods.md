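# Methods

`splicevar` predicts whether an exonic single-base substitution disrupts
pre-mRNA splicing and, when it does, proposes the disrupted mechanism. This
note records the model, the numerical choices, what the synthetic data
emulate, and the limits of what the tests demonstrate.

## Variant anchoring and coordinates

All coordinates are 0-based half-open internally; VCF and GTF conventions
are converted at the I/O boundary, and the round trip is tested. A variant
is anchored to a *target exon*: among transcripts whose exons contain it,
the transcript with the most exons wins, ties broken by lexicographic
transcript id. This rule is a package convention — annotation databases do
not dictate one — chosen purely for determinism. Everything downstream is
computed on the transcript's sense strand; minus-strand loci are
reverse-complemented (alleles included) before any feature sees them, and a
mirror-locus test asserts the two strands give identical contexts.

Distances to splice sites give the exon-terminal base distance 0; a central
tie resolves to the donor side. "Constitutive exon" means the identical
genomic interval occurs in every transcript of the gene.

Variants failing any feature prerequisite — not exonic, reference mismatch,
conservation value missing, truncated 11 bp window, or a terminal exon
without a scored natural site — are excluded with a logged reason rather
than imputed, so assembled feature vectors never contain missing values.

## Feature set (996 columns)

Per variant: distance to the nearest splice site; the nine-category ESR
change profile; counts of wild-type ESE/ESS hexamers overlapping the site;
four ESR-HS scores (below); 3-mer and 4-mer spectra of the 11 bp window
around the variant for the wild-type allele, the mutant allele, and their
difference (960 columns — counts, not frequencies, which is lossless);
change in natural splice-site strength; maximum cryptic-site score; the two
conservation scores; wild-type donor/acceptor strengths; flanking intron
lengths; exonic ESE/ESS densities over the first/last 50 bp (the whole exon
when shorter than 100 bp) and intronic ESS densities over 100 bp flanks
(density = fraction of hexamer windows in the catalog; regions shorter than
one hexamer report 0 with an "undefined" flag); and the exon/gene scalars
(GC%, exon size, internal-coding and constitutive flags, exon and
transcript counts).

### ESR change and ESR-HS

Every 6-mer window overlapping the substitution (six for interior
positions) is classified ESE / ESS / neutral against the hexamer catalog
for both alleles, giving the nine transition counts. Counts, not binary
indicators, are emitted; binarizing is a trivial view.

The ESR hexamer score contrasts a disease corpus with a neutral corpus:

    ESR-HS(t, k, j) = log2(S[t,k,dis] / S[t,k,neu]) + log2(H[t,k,j,dis] / H[t,k,j,neu])

with t a transition type (ESE loss/gain, ESS loss/gain), k the lost (for
losses, wild-type) or gained (for gains, mutant) hexamer, and j in 0..5 the
substituted position. S and H are normalized counts with a pseudocount of
1 added to every cell (the magnitude is configurable; 1 is the smallest
integer choice and keeps all entries strictly positive, so the score is
always finite). The hexamer universe of a transition type is the
corresponding catalog (ESE catalog for ESE loss/gain, ESS for ESS
loss/gain). An ESE→ESS window realizes both an ESE loss and an ESS gain.

A variant can realize the same transition type in several overlapping
windows; the per-variant feature takes the **maximum** score over
contributing windows (strongest signal; `sum` is available), 0 when no
window realizes the type.

### Splice-site scoring

Window geometry is the field's standard: donor = 3 exonic + 6 intronic
bases, acceptor = 20 intronic + 3 exonic. The scoring backend is pluggable
(anything with `window_length` and `score()`); externally supplied score
tables are accepted as TSV, and the default backend is a log2-odds
position-weight matrix (pseudocount 1, uniform background) trained on the
annotation's own junction windows, which keeps the toolkit self-contained.
The natural-site delta is mutant minus wild-type for any natural window the
variant touches (0 otherwise; a tiny exon whose variant sits in both
windows reports the larger-magnitude delta with a flag). The cryptic score
is the maximum over all donor- and acceptor-shaped windows containing the
variant on the mutant allele, excluding windows whose implied junction
coordinate equals an annotated junction — coordinate identity, not window
overlap, defines "the natural site".

### Conservation

Two per-base tracks are consumed from a bedGraph dialect (contig, start,
end, value; 0-based half-open): a base-wise score that may be negative and
a conserved-element probability validated to [0,1]. Conservation is looked
up, never computed; missing positions exclude the variant.

## Classifier: balanced Random-Forest ensemble

Negatives usually outnumber positives by a wide margin. The negatives are
partitioned into balanced subsets of size `n_pos` (shuffled, without
replacement; the remainder subset is topped up by re-sampling already-used
negatives — dropping the remainder is available), one forest is trained per
subset against the full positive set, and the **general score** is the
arithmetic mean of per-forest positive-class probabilities. A general score
≥ 0.60 calls a SAV. When self-training leaves positives in the majority the
same partition logic runs in the mirrored direction.

Forest defaults: 500 trees, `max_features=0.1`, `min_samples_leaf=3`,
out-of-bag scoring enabled, all recorded in the model archive together with
the seed and a feature-schema hash. The feature budget is larger than the
usual `sqrt(p)` heuristic because ~96% of the columns are sparse k-mer
counts: at `sqrt(996) ≈ 31` features per split, a split rarely sees any of
the few dozen strongly informative columns. `min_samples_leaf=3` keeps leaf
votes graded instead of 0/1, which sharpens the averaged probabilities.
Class probability per forest is scikit-learn's mean of per-tree leaf
distributions.

## Three-iteration training regimen

* **Iter. 1** — train on the initial labeled sets.
* **Iter. 2** — remove negatives the Iter.1 model scores ≥ 0.80 and
  retrain. Training negatives are scored *honestly*: a base model that
  contained the negative in its training subset contributes its out-of-bag
  probability instead of the fitted one. A fully grown forest reproduces
  its own training labels, so fitted probabilities can never cross the
  removal threshold for in-training negatives; with a single balanced
  subset the cleaning step would otherwise be a no-op by construction.
* **Iter. 3** — score the unlabeled pool with the Iter.2 model; examples
  ≥ 0.90 join the positives, ≤ 0.10 the negatives; retrain.

The 0.80/0.90/0.10 thresholds are defaults of `IterationConfig`; every
removal and addition is journalled with the score that justified it, and a
replay test asserts the ledgers reconstruct the final sets exactly.

## Mechanism hypotheses

For a predicted SAV, four properties are compared with their distributions
over predicted-neutral variants (mean/sd require ≥ 30 variants and strictly
positive sd):

| mechanism | property | tail |
|---|---|---|
| natural splice site loss | natural-site delta | lower |
| cryptic splice site activation | max cryptic score | upper |
| exon skipping | ESE-loss + ESS-gain burden | upper |
| exon retention | ESS-loss + ESE-gain burden | upper |

Burdens are count-weighted ESR-HS values (each transition count times the
variant's ESR-HS feature for that type; dual transitions such as ESE→ESS
contribute to both terms). One-sided normal tails convert Z to P; P < 0.05
marks a hypothesis confident; hypotheses return sorted by ascending P. The
exon-retention hypothesis is only evaluated for non-constitutive target
exons — retention of an exon present in every isoform is not a coherent
outcome.

## Evaluation conventions

"Accuracy" is the mean of sensitivity and specificity — the convention of
the splicing-prediction benchmarking literature — with the standard
(TP+TN)/N also reported. MCC and FPR use the usual definitions; metrics
with empty denominators are flagged undefined rather than raised. ROC/AUC
come from scikit-learn (ties get half credit); a hand-written pair-counting
oracle cross-checks the AUC in tests. Feature ranking trains a linear SVM
(standardized inputs) per feature or feature subset under stratified
10-fold CV and compares fold AUCs with those of a per-example
uniform-random control feature by Welch's unpaired t-test,
Bonferroni-corrected over the number of ranked groups; constant features
record AUC 0.5 and skip the test. Fold AUCs from a shared split are
correlated, so the uncorrected test is anti-conservative — the correction
over a realistically sized feature list is what controls the null, and the
null-behavior test exercises exactly that configuration.

## Synthetic data: what it emulates, and what it does not

The generator realizes, from one seeded PCG64 stream, a deterministic
study: multi-exon genes (mixed strands, ~half with a second isoform that
skips one internal exon, making it non-constitutive) with canonical GT..AG
introns, donor/acceptor consensus strong enough for the annotation-trained
PWM to be informative; disjoint ESE/ESS hexamer catalogs (120/80 by
default); conservation tracks defined at every exonic base; and variant
sets with splice-altering variants planted by mechanism:

* **site loss** — donor −1 G>T or acceptor +1 G>C inside the natural
  window (delta ≈ −4 to −6 PWM log-odds);
* **cryptic activation** — a pre-planted 9-mer one substitution away from
  the donor consensus, activated by the variant;
* **exon skipping** — a planted "hot" ESE hexamer converted to a neutral
  hexamer in a constitutive exon;
* **exon retention** — a planted hot ESS hexamer converted to neutral in a
  non-constitutive exon.

Hot hexamers each carry one fixed (position, alt) recurrent substitution,
the way recurrent disease mutations concentrate at particular motif
positions; this is what gives the positional H table signal. Hexamers whose
sequence is fully determined by the shared site-loss/cryptic plant contexts
are excluded from catalog sampling, otherwise every such plant would carry
an identical incidental ESR transition and contaminate the disease corpus
with a non-ESR signal.

Neutral variants are rejection-sampled: outside planted slots, natural-site
delta capped at |0.75|, mutant cryptic score capped at 2.0. A 5% quota sits
at low-information natural-window positions so the predicted-neutral
reference distribution of the delta property has nonzero spread (a
zero-variance reference is an error by contract). True-SAV sites draw
conserved-element probabilities from Beta(5,2) against a Beta(2,5)
background and base-wise conservation from N(1.5,1) against N(0,1),
emulating the empirical association between splice-disrupting variants and
conserved sequence. A configurable number of true SAVs (default 5, drawn
from the unambiguous mechanisms with pairwise-distinct signatures) is
presented as mislabeled negatives and duplicated into the unlabeled pool
under fresh ids, with a sidecar key mapping back — this realizes both "the
pool contains no labeled ids" and "the mislabeled examples are present in
the pool".

The default study is 500 SAV / 600 SNV labeled (the benchmark trains on
300/500 — negatives in the majority, the regime the balanced ensemble is
designed for — and holds out 100/100) plus a 205-example unlabeled pool.

What passing the synthetic-recovery tests shows: the pipeline's plumbing is
sound end to end — features carry the planted signal through the production
file formats, the ensemble converts it into calibrated-enough scores for
the 0.60/0.80/0.90 decision points, self-training repairs label noise it
was designed to repair, and mechanism Z-scores attribute the planted
mechanism. What it does **not** show: performance on real genomes. The
fixtures have no alternative splice-site diversity, no compositional
heterogeneity (uniform base background), conservation planted directly at
variant sites rather than arising from alignment depth, and planted effects
larger and cleaner than most real regulatory variation. Published
corpus-scale error rates are not reproducible at desk scale and are not
claimed.

## Degenerate inputs and tie-breaks

* Hexamers containing N classify neutral with a masked flag; other
  characters are errors.
* ESE/ESS catalog collisions error by default
  (`prefer-ese|prefer-ess|drop` available).
* Equal-magnitude deltas from both natural windows: donor/acceptor choice
  falls to the larger magnitude, flagged `both_windows`.
* An empty unlabeled pool makes Iter.3 a warned copy of Iter.2; removal
  thresholds that empty the negative set raise.
* Mechanism P-values are clamped to the open interval (0,1) so downstream
  sorting never sees exact 0/1 from extreme Z.

## Problem sizes

Default synthetic study: ~100 genes (~1,300 planted variants) on two
contigs; the full benchmark — generation, featurization of ~1,300 variants,
three ensemble trainings at 500 trees, evaluation and mechanism scoring —
completes in well under a minute on one CPU. The test suite's oracle-
equivalence checks use 500–1,000 random fixtures per scanner.
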