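# varguide

Variant-aware CRISPR-Cas9 off-target detection and activity scoring.

CRISPR-Cas9 cleaves not only its intended target but also genomic sites that
resemble the guide RNA, and the single-nucleotide variants and small INDELs
an individual carries can create or destroy such sites. `varguide` is a
toolkit for researchers designing guides for personalized applications: it
builds an individualized "variant genome" from a VCF, searches both the
reference and the variant sequences for sites within a mismatch budget of a
guide (up to 8 mismatches over the 20-bp protospacer, with configurable PAM
motifs), merges and filters the two hit sets with VCF back-references, and
scores candidate sites with the MIT position-weight score, a CFD-style
penalty product, and a trainable Random-Forest activity model.

## How it works

**Variant genome.** Variants closer than 23 bp (so a single protospacer+PAM
site could span them) are clustered, and each cluster is expanded into
sequences with 22-bp reference flanks. Phased genotypes give one sequence
per haplotype; unphased heterozygotes are expanded into every non-empty
allele combination (2ⁿ − 1 sequences for n hets; homozygous-alt variants are
fixed in all of them). Each sequence carries an offset map lifting its
positions back to reference coordinates.

**Search.** Sites are found with a bidirectional FM-index and a pigeonhole
search scheme: the protospacer is tiled into k+1 pieces, each piece is
located exactly in the index, and candidates are verified under
"first error-free piece" constraints so every site within the budget is
enumerated exactly once. A sliding-window Hamming scan
(`brute_force_search`) serves as the independent oracle; the two are tested
for exact agreement. Mismatches are counted on the protospacer only; the
3-bp PAM (NGG by default, e.g. NGG+NGA for relaxed searches) is checked
separately and its degenerate positions never count as mismatches.

**Scoring.** For a guide g and off-target o with mismatched positions
p₁..pₘ (numbered 1..20 from the PAM-distal end):

* MIT score: `∏ᵢ (1 − W_pᵢ) × 1/(((19 − d̄)/19)·4 + 1) × 1/m²`, where `W` are
  the published position weights and `d̄` is the mean pairwise distance
  between mismatch positions (perfect match → 1; single mismatch → distance
  term 1).
* CFD score: product of per-position mismatch penalties and a PAM-dinucleotide
  penalty from a bundled table (a clearly labelled synthetic reconstruction
  of the published table's structure — see `docs/methods.md`).
* Random Forest: probability of activity from a forest trained on ~460
  features covering mismatch properties (counts, seed-region counts,
  per-position mismatch/transition/transversion indicators), sequence
  context (position-specific mono-/dinucleotides, GC), and the on/off-target
  PAM relationship. The full training procedure is included: balanced
  downsampling of inactives weighted by the actives' mismatch histogram
  (10 repeats), importance averaging, backward feature selection by
  out-of-bag error, and best-repeat final model selection.

## Worked example

```sh
varguide simulate --outdir demo --genome-length 8000 --seed 5
varguide run --genome demo/genome.fa --vcf demo/sample.vcf \
    --guides demo/guides.txt --max-mm 4 --scorer mit --out demo/hits.bed
```

The first command writes a synthetic 8-kb genome with five planted
off-target sites (0–4 mismatches), a phased VCF and a guide file. The
second searches it; the run prints a JSON summary such as

```json
{
 "counts": {
  "reference_hits": 5,
  "variant_hits": 4,
  "merged": 8,
  "filtered_by_merge": 1,
  "retained_after_threshold": 8
 }
}
```

meaning five sites were found in the reference, four in the variant genome,
and after lifting, deduplication and filtering eight distinct records
remain (heterozygous variants legitimately leave both the reference and the
variant version of a site in play). `demo/hits.bed` is BED6 plus extra
columns — sequence, mismatch count and positions, source
(`reference`/`variant`) and the VCF IDs of the variants a site contains:

```text
chr1  3705  3728  guide1  38    +  ACTTATAAGCCATGGAATCTTGG  2  1;6     reference  .
chr1  3705  3728  guide1  10    +  ACTTATAAGCCTTGGAATCTTGG  3  1;6;12  variant    var0007
chr1  4296  4319  guide1  1000  +  GCTTAAAAGCCATGGAATCTGGG  0  .       reference  .
```

The BED score column is the chosen score scaled to 0–1000 (here the MIT
score: the perfect match scores 1000, the 3-mismatch variant site 10).
Guides with a declared origin locus have their own on-target match removed;
perfect matches elsewhere are kept and flagged.

To train an activity model on a labeled table (fixture-generated or your
own, TSV with `on_target`, `off_target`, `n_mismatches`, `label`):

```sh
varguide train --table training.tsv --out model.joblib --seed 1
varguide run ... --scorer rf --model model.joblib --threshold 0.5 --out hits.bed
```

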