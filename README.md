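# splicevar

Prediction of exonic single-base substitutions that disrupt pre-mRNA
splicing, with a hypothesis of the disrupted mechanism.

Most variant-effect tools score a coding substitution by what it does to
the protein, and quietly treat same-sense changes as neutral. But exons
carry their own splicing code: exonic splicing enhancers and silencers
(ESE/ESS hexamers), the exonic thirds of the donor and acceptor sites, and
sequence that can turn into a cryptic splice site after one substitution. A
missense, same-sense or nonsense variant can therefore cause exon skipping,
exon retention, natural-site loss or cryptic-site activation — often the
actual mechanism of pathogenicity. `splicevar` is for geneticists and
method developers who want to prioritize such splice-altering variants
(SAVs) in exome/genome call sets and to train or re-train the classifier on
their own corpora.

## The method

For a variant anchored to its target exon (transcript-aware,
strand-resolved), the package extracts the feature set of the
splicing-impact literature: distance to the nearest splice site; the
nine-category **ESR change** profile (ESE/ESS/neutral transitions of every
hexamer window overlapping the variant); wild-type ESE/ESS overlap counts;
the **ESR hexamer score**

&nbsp;&nbsp;&nbsp;&nbsp;ESR-HS(t, k, j) = log₂(S₍t,k,dis₎/S₍t,k,neu₎) + log₂(H₍t,k,j,dis₎/H₍t,k,j,neu₎)

contrasting pseudocounted hexamer (S) and substituted-position (H)
frequencies between a disease and a neutral corpus; spectrum-kernel 3-/4-mer
counts over an 11 bp window for both alleles; natural splice-site strength
and its mutant-minus-wild-type delta plus a cryptic-site scan (MaxEnt-style
windows — donor 3+6, acceptor 20+3 — with a pluggable scorer; the built-in
fallback is a PWM trained on the annotation's own junctions); base-wise and
element-probability conservation lookups; and exon/gene descriptors
(ESE/ESS densities, GC%, sizes, constitutive and internal-coding flags,
exon and isoform counts).

Classification uses a **balanced Random-Forest ensemble**: negatives are
partitioned into positive-sized subsets, one forest per subset, and the
mean positive-class probability — the *general score* — calls a SAV at
≥ 0.60. Noisy negative sets are handled by a three-iteration, semi-
supervised regimen: Iter.2 removes negatives the model confidently flags as
SAVs (honest out-of-bag scoring), Iter.3 self-trains from an unlabeled pool
(add ≥ 0.90 as positives, ≤ 0.10 as negatives). For each predicted SAV,
mechanism hypotheses compare the natural-site delta, the cryptic maximum
and the ESE/ESS loss-gain burdens against their distributions over
predicted-neutral variants: Z-scores with one-sided P-values, confident at
P < 0.05, exon retention only offered for non-constitutive exons.

A deterministic synthetic-data module generates complete study bundles
(FASTA, GTF, hexamer catalogs, conservation bedGraphs, labeled/unlabeled
variant sets with planted mechanisms and mislabeled negatives), so the
whole pipeline builds and tests offline.

## Worked example

Metric arithmetic on a benchmark confusion matrix (TP=121, FP=7, TN=76,
FN=60 on a 264-variant evaluation set):

```python
from splicevar.evaluation import ConfusionCounts, metrics

rep = metrics(ConfusionCounts(tp=121, fp=7, tn=76, fn=60))
for k, v in rep.rounded().items():
    print(f"{k:>24}: {v}")
```

```
         sensitivity_pct: 66.9
         specificity_pct: 91.6
                 fpr_pct: 8.4
            accuracy_pct: 79.2
   accuracy_standard_pct: 74.6
                 auc_pct: None
                     mcc: 0.54
```

Sensitivity 66.9% with specificity 91.6% reflects the deliberately
conservative 0.60 call threshold: two of three true SAVs are recovered
while fewer than one in ten neutral variants is miscalled. The headline
`accuracy_pct` is the mean of sensitivity and specificity (the field's
convention for imbalanced evaluation sets — the plain (TP+TN)/N is also
shown), and MCC 0.54 summarizes the same matrix on a −1..+1 scale. No AUC
is reported because only calls, not scores, went in.

End to end on a simulated bundle, from the shell:

```bash
splicevar simulate -o demo --seed 7 --n-genes 20 --n-sav 40 --n-snv 50 --n-unlabeled 12
splicevar train   --fasta demo/genome.fa --gtf demo/annotation.gtf \
                  --ese demo/ese.txt --ess demo/ess.txt \
                  --phylop demo/basewise.bedgraph --phastcons demo/element.bedgraph \
                  --variants demo/labeled.tsv --seed 7 --n-trees 100 -o demo/model.joblib
splicevar predict -m demo/model.joblib --fasta demo/genome.fa --gtf demo/annotation.gtf \
                  --phylop demo/basewise.bedgraph --phastcons demo/element.bedgraph \
                  --vcf demo/unlabeled.vcf -o demo/annotated.vcf
```

```
trained 2-model ensemble on 90 variants (0 excluded)
annotated 17 variants (0 excluded) -> demo/annotated.vcf
```

The annotated VCF carries the general score and call per record:

```
chr1	7333	v000042_u	G	T	.	.	SPV_SCORE=0.532914;SPV_CALL=SNV
chr1	7606	v000043_u	C	G	.	.	SPV_SCORE=0.667707;SPV_CALL=SAV
```

`splicevar featurize` writes the full 996-column feature table, and
`splicevar mechanism` emits mechanism hypotheses (mechanism, Z, P,
confident) for predicted SAVs given a predicted-neutral reference pool. The
library API (`splicevar.run_iterations`, `splicevar.rank_features`, …)
exposes the same machinery with ledgers and fold-level detail.

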