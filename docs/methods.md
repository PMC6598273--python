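# Methods

## Problem and model

Cas9 tolerates imperfect pairing between its guide RNA and genomic DNA, so
a 20-bp protospacer followed by a permissive PAM can be cleaved even with
several mismatches. `varguide` treats off-target detection as approximate
string matching under a Hamming model: a site is any genomic 23-mer whose
20-bp protospacer is within a mismatch budget k of the guide (default and
maximum k = 8) and whose 3-bp PAM satisfies one of a set of IUPAC motifs.
Mismatches are counted on the protospacer only; degenerate PAM positions
never count. There is no gapped (bulge) alignment between guide and
off-target — that is a deliberate scope limit of the Hamming model, shared
with the mismatch-position numbering (1..20 from the PAM-distal end, strand
independent).

Individual variation enters through the variant genome: each variant (or
cluster of nearby variants) is expanded into variant-bearing sequences with
22-bp reference flanks, which are searched alongside the reference. 22 bp
is the largest distance at which a variant can still fall inside a 23-bp
site together with a flank boundary base, and for the same reason two
variants are clustered when the gap between their reference footprints is
at most 22 bp (so every pair co-occupiable by one site shares a window).

## Variant-genome construction

* Phased clusters emit one sequence per haplotype carrying that haplotype's
  alleles; identical haplotype choices collapse into one labelled sequence.
* Clusters containing unphased heterozygotes are expanded combinatorially:
  homozygous-alt variants are fixed, every subset of the hets is toggled,
  and the all-reference combination is omitted because the reference scan
  already produces those matches (duplicates are removed at merge anyway).
  A cap of 10 hets per cluster (1023 combinations) guards against
  explosion; beyond it the cluster is processed one variant at a time with
  a warning.
* Combinations containing variants with overlapping reference footprints
  are skipped — conflicting alleles are treated as mutually exclusive.
* Hom-ref genotypes are skipped on VCF ingestion (no sequence change);
  multi-allelic records are split into bi-allelic variants first.
* Every allele sequence carries an offset map to reference coordinates.
  Inserted bases lift to the insertion anchor (the VCF anchor base), which
  is also the convention used when a hit must be reported inside an
  insertion: such hits are kept and flagged `lifted_inexact` rather than
  dropped.

One consequence of clustering on reference coordinates: a deletion can
bring two clusters that are > 22 bp apart on the reference to within one
site length on the haplotype; such straddling sites are outside the
windows' coverage guarantee. With the small, sparse INDELs the generator
plants (≤ 5 bp) this is a negligible corner, but it is a real limitation
for dense or large deletions.

## Search

The index is a bidirectional FM-index: suffix arrays of the concatenated
text and of its reverse (built by Manber–Myers prefix doubling), full
occurrence tables, and the standard synchronized interval update that lets
a match be extended by one character to the left or right in any order.
Sequences are concatenated with separator characters that match nothing,
so matches cannot straddle boundaries.

Error-tolerant search uses a pigeonhole scheme: the protospacer is tiled
into k + 1 contiguous pieces of near-equal length; search i enumerates
exactly the sites whose first error-free piece is piece i (piece i exact,
every earlier piece ≥ 1 error, total ≤ k). These conditions are mutually
exclusive and, by pigeonhole, exhaustive, so every in-budget site is found
exactly once with no deduplication step. The seed piece is located exactly
via the index; candidate windows are then verified against the text in a
single vectorized pass that applies the per-piece error constraints and
the PAM masks. Minus-strand sites are searched as the reverse complement
pattern and reported on the reference interval they occupy, with the
protospacer read 5'→3' on the target strand. A genomic N matches no guide
base (it counts as a mismatch within budget) and satisfies no PAM position
except an explicit N.

Correctness is defined operationally: `brute_force_search`, an independent
sliding-window Hamming scan, is the oracle, and the test suite asserts set
equality across genomes, budgets 0..8 and PAM sets. The scheme's
exactly-once property is additionally checked by enumerating error
patterns at small k. Optimality of the scheme (minimal index steps) is a
performance property and not pursued; the chosen pieces keep fixture-scale
searches in milliseconds.

### Merge and filter

1. Reference hits overlapping variants are removed only when the reference
   sequence under the hit exists on *no* haplotype: homozygous-alt variants
   remove it, a single phased het does not (the other haplotype still
   carries the reference allele), and two phased hets on opposite
   haplotypes jointly do. Unphased hets are conservatively assumed to leave
   a reference haplotype.
2. Variant hits are lifted through the offset maps, tagged with the IDs of
   the member variants their footprint overlaps, and dropped when they
   overlap none (the reference scan covers pure-flank matches).
3. Duplicates at the same lifted locus and strand across combinations
   collapse to one record keeping the fewest-mismatch version and the
   union of variant IDs.
4. A hit is "the on-target" only if it has 0 mismatches *and* sits at the
   guide's declared origin locus; identical perfect matches elsewhere are
   retained and flagged `perfect_match`. Without a declared origin nothing
   is removed.

## Scoring

* **MIT score** uses the published 20 position weights and the formula
  `∏(1 − W_p) × 1/(((19 − d̄)/19)·4 + 1) × 1/m²`. With m = 1 the mean
  pairwise distance d̄ is undefined; the distance term is set to 1
  (equivalently d̄ = 19), matching standard implementations. Scores are
  reported on the 0–1 scale.
* **CFD score** multiplies per-(position, guide base, off-target base)
  penalties and a PAM penalty keyed by the last two PAM bases. The bundled
  table, `data/cfd_table_synthetic.json`, is a synthetic reconstruction —
  the published supplementary table is not redistributed here — built from
  three structural facts of the published model: penalties decay toward
  the PAM (position factor 1.0 → 0.2 linearly), transitions are tolerated
  more than transversions (0.55 vs 0.30) with extra leniency for the two
  wobble-like pairings (guide G vs off-target A 0.70; guide T vs off-target
  C 0.65), and non-NGG PAM dinucleotides are strongly penalized (the
  widely quoted dinucleotide values). Matched positions score 1; a missing
  table entry raises an explicit lookup error, never a silent 0. Any table
  in the same JSON layout can be supplied instead.
* **Feature schema "v1"** (462 named features): mismatch properties
  (total, seed = positions 9..20, non-seed, mean pairwise mismatch
  distance, 20 per-position mismatch indicators, 20 + 20
  transition/transversion indicators), off-target sequence context (80
  position-specific mononucleotide indicators, 304 dinucleotide
  indicators, GC content), and the on/off-target PAM relationship (first
  PAM base match indicator, 12 PAM one-hot indicators). The schema is
  versioned and its length is recorded in model metadata; the published
  model's exact 443-entry list lives in a supplement that is not
  reproduced, so this schema is a faithful implementation of the three
  stated feature families rather than a literal transcription.

## Training

* Downsampling draws inactives without replacement so each repeat's
  per-mismatch-count histogram equals the actives' histogram; bins with an
  insufficient pool are filled to availability with a reported shortfall.
  10 repeats, each seeded from `(seed, repeat)`.
* Forests are scikit-learn `RandomForestClassifier` with 500 trees,
  `sqrt(p)` features per split, OOB scoring, one seed per repeat
  (hyperparameters are recorded in model metadata; the original
  procedure's are unstated).
* Backward selection retrains after every single-feature removal, dropping
  the feature the *current* model deems least important (ties broken by
  the averaged ranking, then name), and records the OOB error curve. It
  runs on repeat 1's dataset with 150-tree forests — one representative
  dataset and a lighter forest keep the ~460-step loop at desk scale —
  and the winning set (minimum OOB, ties to the smaller set) is then
  refitted on all repeats at full size.
* The final model is the repeat with the lowest OOB error (ties to the
  lowest index), packaged with seeds, per-repeat OOB errors and schema
  metadata, and serialized with joblib.
* Training defaults to canonical-PAM (NGG) sites only, with a flag to
  include all; sites beyond 8 mismatches are excluded.
* Concentration-aware evaluation groups test sites by their minimal active
  concentration tier and reports the mean predicted probability per tier.

## Synthetic data and what passing tests show

The generators plant everything the pipeline must later find: genomes are
i.i.d. with a target GC content (default 0.41, a genome-like value);
off-target sites are written into non-overlapping windows with exact
realized mismatch counts and concrete PAMs on either strand; variants are
consistent with the genome and optionally placed within window reach of
planted sites; labeled tables follow an explicit activity rule — active
iff ≤ 2 seed mismatches and ≤ 5 total — with a minimal-active-concentration
tier from {4, 16, 64, 256} nM that is monotone in the rule margin. The
64 nM tier boundary doubles as the standard labeling threshold for
concentration-resolved tables.

This establishes correctness of the machinery (search equals the oracle,
variant sites are created/destroyed exactly as haplotype reconstruction
dictates, the trainer recovers a planted rule with cross-validated AUC
≥ 0.9 and keeps the informative features through backward selection). It
does not establish biological performance: real cleavage activity is not a
crisp threshold rule, real genomes are not i.i.d., and the synthetic CFD
table does not reproduce published penalty values. Numbers measured on
fixtures characterize the software, not Cas9.

## Numerical and degenerate-input choices

* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; fixed seeds give byte-identical FASTA/VCF/TSV/BED outputs.
* Problem sizes used by the acceptance studies: 10–100 kb genomes for the
  search-oracle study, a 40-kb individual for the variant study, 120
  actives over a 1500-site pool for training — sizes chosen so a complete
  run stays at desk scale on one CPU.
* Ties: importance ranking by (importance desc, name), final model by
  lowest repeat index, backward selection by (importance, averaged rank,
  name).
* Empty inputs fail loudly (index over no sequences, single-class
  training, guide length ≠ 20/23, thresholds outside [0, 1], VCF REF not
  matching the genome).
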