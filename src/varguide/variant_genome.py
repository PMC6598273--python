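"""Construction of the individualized "variant genome".

Variants from a VCF are clustered when they are close enough to be covered by
a single 23-bp target site, and each cluster is expanded into variant-bearing
sequences with 22-bp flanks taken from the reference.  For phased input one
sequence per haplotype is emitted; for unphased heterozygous variants every
possible combination of alleles is emitted (the all-reference combination is
omitted — the reference-genome scan already covers it).  Every emitted
sequence carries an offset map lifting each of its positions back to a
reference coordinate, with inserted bases lifting to their insertion anchor.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .fixtures import ConsistencyError, GenomeSequence, Variant

FLANK = 22          # sites are 23 bp, so a variant can sit up to 22 bp away
MAX_GAP = 22        # two variants co-occupiable by one 23-mer iff gap <= 22
MAX_HET_PER_CLUSTER = 10


class OrderingError(ValueError):
    """Input variants are not sorted by (contig, pos)."""


@dataclass(frozen=True)
class AlleleSequence:
    """One variant-bearing sequence of a window.

    ``offsets[i]`` is the reference coordinate of sequence position ``i``;
    positions inside an insertion map to the insertion's anchor base.
    """

    label: str
    seq: str
    offsets: np.ndarray
    variants: tuple[Variant, ...]


@dataclass(frozen=True)
class VariantWindow:
    """A cluster of variants with 22-bp flanks and its allele sequences."""

    contig: str
    ref_start: int
    ref_end: int
    members: tuple[Variant, ...]
    allele_sequences: tuple[AlleleSequence, ...]

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(v.vcf_line_id for v in self.members)


def read_vcf(path, skip_hom_ref: bool = True) -> list[Variant]:
    """Read a VCF into bi-allelic :class:`Variant` records.

    Multi-allelic records are split; hom-ref and missing genotypes are
    skipped (they carry no sequence change).  The first sample is used.
    """
    import pysam

    variants: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None:
                continue
            gt_raw = rec.samples[samples[0]]["GT"] if samples else (1, 1)
            phased = rec.samples[samples[0]].phased if samples else True
            if gt_raw is None or any(a is None for a in gt_raw):
                continue
            for ai, alt in enumerate(rec.alts, start=1):
                if alt is None or alt.startswith("<") or alt == rec.ref:
                    continue
                gt = tuple(1 if a == ai else 0 for a in gt_raw)
                if skip_hom_ref and sum(gt) == 0:
                    continue
                vid = rec.id or f"{rec.chrom}_{rec.pos}_{rec.ref}_{alt}"
                if len(rec.alts) > 1:
                    vid = f"{vid}.{ai}"
                variants.append(Variant(rec.chrom, rec.pos, rec.ref, alt,
                                        gt, phased, vid))
    return variants


def cluster_variants(variants: list[Variant],
                     max_gap: int = MAX_GAP) -> list[list[Variant]]:
    """Group variants whose pairwise reference gaps chain within ``max_gap``.

    The gap between consecutive variants is measured from the last reference
    base of the earlier footprint to the first of the later one, so two SNVs
    at 1-based positions p and q have gap q - p.  Clusters are maximal under
    transitive chaining.
    """
    keys = [(v.contig, v.pos) for v in variants]
    if keys != sorted(keys):
        raise OrderingError("variants must be sorted by (contig, pos)")
    clusters: list[list[Variant]] = []
    for v in variants:
        if clusters:
            prev = clusters[-1][-1]
            if v.contig == prev.contig and v.start0 - (prev.end0 - 1) <= max_gap:
                clusters[-1].append(v)
                continue
        clusters.append([v])
    return clusters


def _apply_variants(genome: GenomeSequence, start: int, end: int,
                    chosen: tuple[Variant, ...]) -> tuple[str, np.ndarray]:
    """Build the sequence for [start, end) with ``chosen`` variants applied,
    plus the per-position reference-coordinate map."""
    pieces: list[str] = []
    offsets: list[np.ndarray] = []
    cursor = start
    for v in sorted(chosen, key=lambda v: v.pos):
        if genome.seq[v.start0:v.end0] != v.ref:
            raise ConsistencyError(
                f"{v.vcf_line_id}: REF {v.ref!r} does not match the genome "
                f"at {v.contig}:{v.pos}")
        pieces.append(genome.seq[cursor:v.start0])
        offsets.append(np.arange(cursor, v.start0))
        pieces.append(v.alt)
        # shared leading bases (the anchor) lift 1:1; extra inserted bases
        # lift to the anchor coordinate, deleted bases simply vanish
        n_shared = min(len(v.ref), len(v.alt))
        alt_off = np.empty(len(v.alt), dtype=np.int64)
        alt_off[:n_shared] = np.arange(v.start0, v.start0 + n_shared)
        alt_off[n_shared:] = v.start0 + n_shared - 1
        offsets.append(alt_off)
        cursor = v.end0
    pieces.append(genome.seq[cursor:end])
    offsets.append(np.arange(cursor, end))
    return "".join(pieces), np.concatenate(offsets)


def _overlapping(chosen: tuple[Variant, ...]) -> bool:
    ordered = sorted(chosen, key=lambda v: v.start0)
    return any(b.start0 < a.end0 for a, b in zip(ordered, ordered[1:]))


def expand_unphased(cluster: list[Variant]) -> list[tuple[str, tuple[Variant, ...]]]:
    """Enumerate allele combinations for a cluster with unphased hets.

    Hom-alt variants are fixed in every combination; each subset of the het
    variants is toggled, and the all-reference combination is dropped.  A
    cluster with n hets and no hom-alts therefore yields 2^n - 1 labeled
    combinations.  Combinations containing mutually overlapping variants are
    skipped (conflicting alleles cannot co-occur).
    """
    homs = tuple(v for v in cluster if v.is_hom_alt)
    hets = [v for v in cluster if not v.is_hom_alt]
    if len(hets) > MAX_HET_PER_CLUSTER:
        warnings.warn(
            f"cluster with {len(hets)} het variants exceeds the combination "
            f"cap ({MAX_HET_PER_CLUSTER}); processing per single variant")
        combos = [(v,) for v in cluster]
    else:
        combos = []
        for r in range(len(hets) + 1):
            for subset in itertools.combinations(hets, r):
                chosen = homs + subset
                if chosen:
                    combos.append(chosen)
    out = []
    for chosen in combos:
        if _overlapping(chosen):
            continue
        label = "+".join(v.vcf_line_id for v in
                         sorted(chosen, key=lambda v: v.pos))
        out.append((label, chosen))
    return out


def _phased_combinations(cluster: list[Variant]) -> list[tuple[str, tuple[Variant, ...]]]:
    ploidy = max(len(v.genotype) for v in cluster)
    by_choice: dict[tuple[str, ...], list[int]] = {}
    for h in range(ploidy):
        chosen = tuple(v for v in cluster
                       if h < len(v.genotype) and v.genotype[h] == 1)
        if chosen and not _overlapping(chosen):
            key = tuple(v.vcf_line_id for v in chosen)
            by_choice.setdefault(key, []).append(h)
    out = []
    for key, haps in by_choice.items():
        chosen = tuple(v for v in cluster if v.vcf_line_id in key)
        label = ",".join(f"hap{h + 1}" for h in haps)
        out.append((label, chosen))
    return out


def build_windows(genome: GenomeSequence, clusters: list[list[Variant]],
                  flank: int = FLANK) -> list[VariantWindow]:
    """Expand each variant cluster into a flanked, coordinate-mapped window."""
    windows = []
    for cluster in clusters:
        start = max(0, min(v.start0 for v in cluster) - flank)
        end = min(len(genome), max(v.end0 for v in cluster) + flank)
        if all(v.phased or not v.is_het for v in cluster):
            combos = _phased_combinations(cluster)
        else:
            combos = expand_unphased(cluster)
        alleles = []
        for label, chosen in combos:
            seq, offsets = _apply_variants(genome, start, end, chosen)
            alleles.append(AlleleSequence(label, seq, offsets, chosen))
        windows.append(VariantWindow(
            contig=genome.name, ref_start=start, ref_end=end,
            members=tuple(cluster), allele_sequences=tuple(alleles)))
    return windows


def build_variant_genome(genome: GenomeSequence, variants: list[Variant],
                         max_gap: int = MAX_GAP,
                         flank: int = FLANK) -> list[VariantWindow]:
    """Cluster + window construction in one call (variants must be sorted)."""
    return build_windows(genome, cluster_variants(variants, max_gap), flank)


def write_variant_genome(windows: list[VariantWindow], path) -> None:
    """Write allele sequences as multi-FASTA; headers encode contig, the
    reference interval and the variant combination."""
    with open(path, "w") as fh:
        for w in windows:
            for a in w.allele_sequences:
                ids = ";".join(v.vcf_line_id for v in a.variants)
                fh.write(f">{w.contig}:{w.ref_start}-{w.ref_end}|{a.label}|{ids}\n")
                for i in range(0, len(a.seq), 60):
                    fh.write(a.seq[i:i + 60] + "\n")
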