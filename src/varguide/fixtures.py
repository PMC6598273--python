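"""Synthetic data generation: genomes, planted off-target sites, variants and
labeled activity tables.

Everything downstream (variant-genome construction, indexed search, model
training) is exercised on data produced here, so each generator records enough
ground truth to serve as an oracle: planted sites remember their coordinates
and realized mismatches, variants remember the genome bases they replace, and
training tables are labeled by an explicit, known activity rule.

All randomness flows through ``numpy.random.default_rng`` seeded from the
spec, so outputs are byte-identical across runs for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._dna import BASES, IUPAC, is_transition, revcomp

PROTOSPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = PROTOSPACER_LEN + PAM_LEN
SEED_LEN = 12  # PAM-proximal positions 9..20 in 1..20 numbering


class PlacementError(RuntimeError):
    """Raised when requested sites cannot be placed without overlap."""


class ConsistencyError(ValueError):
    """Raised when a variant's REF allele disagrees with the genome."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named contig over {A,C,G,T,N}."""

    name: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic individual: genome plus its variants."""

    genome_length: int = 20_000
    gc_content: float = 0.41
    n_snv: int = 20
    n_indel: int = 2
    indel_max_len: int = 5
    phased: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 100:
            raise ValueError("genome_length must be >= 100")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if self.n_snv < 0 or self.n_indel < 0:
            raise ValueError("variant counts must be non-negative")
        if not 1 <= self.indel_max_len <= 5:
            raise ValueError("indel_max_len must lie in [1, 5]")


@dataclass(frozen=True)
class PlantSpec:
    """What off-target sites to plant for one guide (23-mer: 20 + PAM)."""

    guide: str
    n_sites: int
    mismatch_counts: tuple[int, ...]
    pam_choices: tuple[str, ...] = ("NGG",)
    strand_mix: float = 0.0

    def __post_init__(self) -> None:
        if len(self.guide) != SITE_LEN:
            raise ValueError("guide must be a 23-mer (20-mer protospacer + PAM)")
        if any(not 0 <= m <= 8 for m in self.mismatch_counts):
            raise ValueError("mismatch counts must lie in [0, 8]")
        if not 0.0 <= self.strand_mix <= 1.0:
            raise ValueError("strand_mix must lie in [0, 1]")
        for p in self.pam_choices:
            if len(p) != PAM_LEN or any(c not in IUPAC for c in p):
                raise ValueError(f"invalid PAM motif {p!r}")


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth record of one planted off-target site."""

    start: int            # 0-based leftmost coordinate of the 23-bp window
    strand: str           # '+' or '-'
    protospacer: str      # 20-mer as the guide reads it (5'->3' on target strand)
    pam: str              # realized 3-mer, guide orientation
    mismatch_positions: tuple[int, ...]  # 1..20 from the PAM-distal end


@dataclass(frozen=True)
class Variant:
    """A bi-allelic small variant in VCF conventions (1-based pos)."""

    contig: str
    pos: int
    ref: str
    alt: str
    genotype: tuple[int, ...]
    phased: bool
    vcf_line_id: str

    def __post_init__(self) -> None:
        if not self.ref:
            raise ValueError("ref allele must be non-empty")
        if self.alt == self.ref:
            raise ValueError("alt allele must differ from ref")

    @property
    def start0(self) -> int:
        return self.pos - 1

    @property
    def end0(self) -> int:
        return self.pos - 1 + len(self.ref)

    @property
    def is_het(self) -> bool:
        return 0 < sum(self.genotype) < len(self.genotype)

    @property
    def is_hom_alt(self) -> bool:
        return all(a == 1 for a in self.genotype)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def generate_genome(spec: SyntheticSpec, name: str = "chr1") -> GenomeSequence:
    """Sample an i.i.d. genome with the requested GC content."""
    rng = np.random.default_rng(spec.rng_seed)
    gc = spec.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(list(BASES), size=spec.genome_length, p=p))
    return GenomeSequence(name, seq)


def random_guide(rng: np.random.Generator, pam: str = "NGG") -> str:
    """A random 23-mer guide whose PAM realizes ``pam``."""
    proto = "".join(rng.choice(list(BASES), size=PROTOSPACER_LEN))
    realized = "".join(
        rng.choice(sorted(set(IUPAC[c]) - {"N"})) for c in pam
    )
    return proto + realized


def _mutate(rng: np.random.Generator, base: str) -> str:
    return rng.choice(sorted(set(BASES) - {base}))


def plant_offtargets(
    genome: GenomeSequence,
    plant: PlantSpec,
    seed: int = 0,
    min_gap: int = 1,
) -> tuple[GenomeSequence, list[PlantedSite]]:
    """Overwrite non-overlapping 23-bp windows with near-copies of the guide.

    Each site realizes its requested protospacer mismatch count exactly and a
    PAM drawn from ``plant.pam_choices``; ``strand_mix`` of the sites are
    placed as reverse complements.  Windows containing N are never used.
    Returns the edited genome and the ground-truth records.
    """
    rng = np.random.default_rng(seed)
    guide20 = plant.guide[:PROTOSPACER_LEN]
    seq = list(genome.seq)
    taken: list[tuple[int, int]] = []
    sites: list[PlantedSite] = []
    n_positions = len(seq) - SITE_LEN
    if n_positions <= 0:
        raise PlacementError("genome shorter than one site")
    for i in range(plant.n_sites):
        mm = plant.mismatch_counts[i % len(plant.mismatch_counts)]
        placed = False
        for _attempt in range(200):
            start = int(rng.integers(0, n_positions))
            span = (start - min_gap, start + SITE_LEN + min_gap)
            if any(span[0] < e and s < span[1] for s, e in taken):
                continue
            if "N" in genome.seq[start:start + SITE_LEN]:
                continue
            positions = tuple(sorted(
                int(p) + 1 for p in
                rng.choice(PROTOSPACER_LEN, size=mm, replace=False)
            ))
            proto = list(guide20)
            for p in positions:
                proto[p - 1] = _mutate(rng, guide20[p - 1])
            motif = plant.pam_choices[int(rng.integers(len(plant.pam_choices)))]
            pam = "".join(
                rng.choice(sorted(set(IUPAC[c]) - {"N"})) for c in motif
            )
            site23 = "".join(proto) + pam
            minus = rng.random() < plant.strand_mix
            placed_seq = revcomp(site23) if minus else site23
            seq[start:start + SITE_LEN] = placed_seq
            taken.append((start, start + SITE_LEN))
            sites.append(PlantedSite(
                start=start,
                strand="-" if minus else "+",
                protospacer="".join(proto),
                pam=pam,
                mismatch_positions=positions,
            ))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place site {i + 1}/{plant.n_sites} without overlap"
            )
    return GenomeSequence(genome.name, "".join(seq)), sites


def generate_variants(
    genome: GenomeSequence,
    spec: SyntheticSpec,
    near_sites: list[int] | None = None,
    near_fraction: float = 0.5,
    hom_fraction: float = 0.3,
) -> list[Variant]:
    """Sample SNVs and small INDELs consistent with the genome.

    When ``near_sites`` (0-based positions) is given, ``near_fraction`` of the
    variants are placed within 22 bp of one of those positions so that
    variant windows intersect plantable off-target sites.  Genotypes are
    heterozygous or homozygous-alt; het genotypes are phased iff
    ``spec.phased``.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    occupied: list[tuple[int, int]] = []
    variants: list[Variant] = []
    L = len(genome)

    def pick_pos(footprint: int) -> int | None:
        for _ in range(300):
            if near_sites and rng.random() < near_fraction:
                anchor = int(near_sites[int(rng.integers(len(near_sites)))])
                lo = max(1, anchor - 22)
                hi = min(L - footprint - 1, anchor + SITE_LEN + 22)
                if hi <= lo:
                    continue
                pos = int(rng.integers(lo, hi))
            else:
                pos = int(rng.integers(1, L - footprint - 1))
            if any(pos - 1 < e + 1 and s - 1 < pos + footprint for s, e in occupied):
                continue
            if "N" in genome.seq[pos:pos + footprint]:
                continue
            return pos
        return None

    def genotype() -> tuple[tuple[int, int], bool]:
        if rng.random() < hom_fraction:
            return (1, 1), spec.phased
        gt = (0, 1) if rng.random() < 0.5 else (1, 0)
        if not spec.phased:
            gt = (0, 1)
        return gt, spec.phased

    k = 0
    for _ in range(spec.n_snv):
        pos0 = pick_pos(1)
        if pos0 is None:
            break
        ref = genome.seq[pos0]
        alt = _mutate(rng, ref)
        gt, phased = genotype()
        k += 1
        variants.append(Variant(genome.name, pos0 + 1, ref, alt, gt, phased,
                                f"var{k:04d}"))
        occupied.append((pos0, pos0 + 1))
    for _ in range(spec.n_indel):
        ins = rng.random() < 0.5
        ln = int(rng.integers(1, spec.indel_max_len + 1))
        footprint = 1 if ins else 1 + ln
        pos0 = pick_pos(footprint)
        if pos0 is None:
            break
        anchor = genome.seq[pos0]
        if ins:
            ref = anchor
            alt = anchor + "".join(rng.choice(list(BASES), size=ln))
        else:
            ref = genome.seq[pos0:pos0 + 1 + ln]
            alt = anchor
        gt, phased = genotype()
        k += 1
        variants.append(Variant(genome.name, pos0 + 1, ref, alt, gt, phased,
                                f"var{k:04d}"))
        occupied.append((pos0, pos0 + footprint))
    variants.sort(key=lambda v: (v.contig, v.pos))
    for v in variants:
        if genome.seq[v.start0:v.end0] != v.ref:
            raise ConsistencyError(f"{v.vcf_line_id}: ref allele mismatch")
    return variants


# ---------------------------------------------------------------------------
# Standard-format writers (FASTA 60-col, VCF v4.2, TSV tables)
# ---------------------------------------------------------------------------

def write_fasta(genomes: list[GenomeSequence], path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, len(g.seq), 60):
                fh.write(g.seq[i:i + 60] + "\n")


def write_vcf(variants: list[Variant], path, contigs: dict[str, int],
              sample: str = "SAMPLE") -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for v in variants:
            sep = "|" if v.phased else "/"
            gt = sep.join(str(a) for a in v.genotype)
            fh.write(f"{v.contig}\t{v.pos}\t{v.vcf_line_id}\t{v.ref}\t{v.alt}"
                     f"\t.\tPASS\t.\tGT\t{gt}\n")


# ---------------------------------------------------------------------------
# Labeled activity tables with a planted, recoverable rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityRule:
    """Ground-truth rule: active iff few seed and few total mismatches.

    The seed region (12 bp immediately PAM-proximal, positions 9..20) carries
    the strongest signal in real cleavage data; the rule encodes that so the
    trainer has a recoverable target.  The margin — how far a site sits from
    the decision boundary — drives the synthetic minimal active concentration
    tier: more clearly active sites are detected at lower enzyme
    concentration.
    """

    max_seed_mm: int = 2
    max_total_mm: int = 5

    def margin(self, seed_mm: int, total_mm: int) -> int:
        return min(self.max_seed_mm - seed_mm, self.max_total_mm - total_mm)

    def is_active(self, seed_mm: int, total_mm: int) -> bool:
        return self.margin(seed_mm, total_mm) >= 0

    def concentration_tier(self, seed_mm: int, total_mm: int) -> int | None:
        """Minimal active concentration (nM) from {4,16,64,256}; None = never
        detected.  Monotone: a larger rule margin gives a smaller tier."""
        m = self.margin(seed_mm, total_mm)
        if m >= 2:
            return 4
        if m == 1:
            return 16
        if m == 0:
            return 64
        if m == -1:
            return 256
        return None


def _offtarget_with_mismatches(rng: np.random.Generator, guide: str,
                               seed_mm: int, distal_mm: int) -> tuple[str, int]:
    """Mutate the guide protospacer: ``seed_mm`` mismatches in positions 9..20
    and ``distal_mm`` in 1..8.  Returns (23-mer, total mismatches)."""
    proto = list(guide[:PROTOSPACER_LEN])
    seed_pos = rng.choice(np.arange(8, 20), size=seed_mm, replace=False)
    distal_pos = rng.choice(np.arange(0, 8), size=distal_mm, replace=False)
    for p in np.concatenate([seed_pos, distal_pos]).astype(int):
        proto[p] = _mutate(rng, proto[p])
    return "".join(proto) + guide[PROTOSPACER_LEN:], seed_mm + distal_mm


def generate_training_table(
    n_active: int,
    n_inactive_pool: int,
    rule: ActivityRule | None = None,
    seed: int = 0,
    guide: str | None = None,
    active_total_range: tuple[int, int] = (0, 5),
):
    """Build a labeled off-target table with a known activity rule.

    Returns a pandas DataFrame with columns on_target, off_target,
    n_mismatches, n_seed_mismatches, label, min_active_conc_nM.  Active rows
    get a concentration tier from {4,16,64} nM; inactive rows near the rule
    boundary get 256 nM, the rest are never detected (empty).
    """
    import pandas as pd

    rule = rule or ActivityRule()
    rng = np.random.default_rng(seed)
    if guide is None:
        guide = random_guide(rng, "NGG")
    rows = []
    lo, hi = active_total_range
    for _ in range(n_active):
        while True:
            total = int(rng.integers(lo, hi + 1))
            seed_mm = int(rng.integers(0, min(total, rule.max_seed_mm) + 1))
            if rule.is_active(seed_mm, total) and total - seed_mm <= 8:
                break
        off, total = _offtarget_with_mismatches(rng, guide, seed_mm,
                                                total - seed_mm)
        rows.append((guide, off, total, seed_mm, "active",
                     rule.concentration_tier(seed_mm, total)))
    for _ in range(n_inactive_pool):
        while True:
            seed_mm = int(rng.integers(0, 9))
            total = int(rng.integers(seed_mm, 9))
            if seed_mm > 12 or total - seed_mm > 8:
                continue
            if not rule.is_active(seed_mm, total):
                break
        off, total = _offtarget_with_mismatches(rng, guide, seed_mm,
                                                total - seed_mm)
        rows.append((guide, off, total, seed_mm, "inactive",
                     rule.concentration_tier(seed_mm, total)))
    df = pd.DataFrame(rows, columns=[
        "on_target", "off_target", "n_mismatches", "n_seed_mismatches",
        "label", "min_active_conc_nM"])
    return df


def write_training_table(df, path) -> None:
    df.to_csv(path, sep="\t", index=False)
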