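"""Mismatch-tolerant off-target search over reference and variant sequences.

The index is a bidirectional FM-index (suffix arrays of the text and its
reverse, with rank/occurrence tables), supporting character-by-character
extension of a match to the left or right in any order.  Error-tolerant
search uses a pigeonhole search scheme: the 20-mer protospacer is tiled into
``k + 1`` contiguous pieces and, for each piece, sites whose *first*
error-free piece is that piece are enumerated — the seed piece is located
exactly in the index and candidates are verified against the text with the
per-piece error constraints.  The per-search constraints are mutually
exclusive and jointly exhaustive, so every site within the mismatch budget
is enumerated exactly once.

Correctness is defined by :func:`brute_force_search`, a sliding-window
Hamming scan of both strands, against which the indexed search is tested.

Conventions
-----------
* Mismatches are counted on the 20-mer protospacer only; the PAM (3 bp, 3'
  of the protospacer) is checked separately against a set of IUPAC motifs
  and its degenerate positions never count as mismatches.
* Mismatch positions are reported 1..20 from the PAM-distal end, identically
  on both strands.
* A genomic N never matches any guide base (it counts as a mismatch) and
  satisfies no PAM position other than N.
* Coordinates are 0-based half-open; minus-strand hits are reported on the
  reference interval they occupy, with the protospacer read 5'->3' on the
  target strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._dna import SEP, decode, encode, motif_mask, revcomp, revcomp_motif
from .fixtures import GenomeSequence, Variant
from .variant_genome import AlleleSequence, VariantWindow

PROTO_LEN = 20
PAM_LEN = 3
SITE_LEN = 23
MAX_MM = 8


class GuideError(ValueError):
    """Invalid guide sequence."""


@dataclass(frozen=True)
class PamSet:
    """PAM motifs (3-base IUPAC patterns) accepted 3' of the protospacer."""

    motifs: tuple[str, ...] = ("NGG",)

    def __post_init__(self) -> None:
        for m in self.motifs:
            if len(m) != PAM_LEN:
                raise ValueError(f"PAM motif {m!r} must have length {PAM_LEN}")

    def mask(self, reverse: bool = False) -> np.ndarray:
        """(n_motifs, 3, 6) boolean table over encoded bases; ``reverse``
        gives masks for the reverse-complemented motifs (minus strand)."""
        ms = [revcomp_motif(m) if reverse else m for m in self.motifs]
        return np.stack([motif_mask(m) for m in ms]) if ms else \
            np.zeros((0, PAM_LEN, 6), dtype=bool)


@dataclass(frozen=True)
class OffTargetHit:
    """A candidate off-target site in guide-oriented representation."""

    contig: str
    start: int
    end: int
    strand: str
    protospacer: str
    pam: str
    mismatch_positions: tuple[int, ...]
    n_mismatches: int
    source: str = "reference"
    variant_ids: tuple[str, ...] = ()
    guide_id: str = ""
    flags: tuple[str, ...] = ()
    scores: dict = field(default_factory=dict, compare=False, hash=False)

    @property
    def key(self) -> tuple:
        return (self.contig, self.start, self.strand)


# ---------------------------------------------------------------------------
# Search schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchScheme:
    """A pigeonhole scheme over a tiled pattern.

    ``parts`` tile [0, pattern_len); search ``i`` requires part ``i`` to be
    error-free and every earlier part to carry at least one error ("first
    error-free part"), with the total bounded by ``max_mismatches``.  The
    per-part minima imply the cumulative lower/upper bounds of the searches
    and make the searches disjoint, so each error pattern within budget is
    enumerated exactly once.
    """

    parts: tuple[tuple[int, int], ...]
    max_mismatches: int

    def __post_init__(self) -> None:
        cursor = 0
        for s, e in self.parts:
            if s != cursor or e <= s:
                raise ValueError("parts must tile the pattern contiguously")
            cursor = e

    @property
    def pattern_length(self) -> int:
        return self.parts[-1][1]

    def accepting_searches(self, error_positions: frozenset[int]) -> list[int]:
        """Indices of the searches that accept this 0-based error pattern."""
        if len(error_positions) > self.max_mismatches:
            return []
        out = []
        for i, _ in enumerate(self.parts):
            counts = [sum(1 for p in error_positions if s <= p < e)
                      for s, e in self.parts]
            if counts[i] == 0 and all(c >= 1 for c in counts[:i]):
                out.append(i)
        return out


def default_scheme(max_mismatches: int,
                   pattern_length: int = PROTO_LEN) -> SearchScheme:
    """Balanced tiling into ``max_mismatches + 1`` pieces."""
    n_parts = max_mismatches + 1
    base, extra = divmod(pattern_length, n_parts)
    if base == 0:
        raise ValueError("pattern too short for this mismatch budget")
    parts = []
    cursor = 0
    for i in range(n_parts):
        ln = base + (1 if i < extra else 0)
        parts.append((cursor, cursor + ln))
        cursor += ln
    return SearchScheme(tuple(parts), max_mismatches)


# ---------------------------------------------------------------------------
# Bidirectional FM-index
# ---------------------------------------------------------------------------

def _suffix_array(text: np.ndarray) -> np.ndarray:
    """Manber-Myers prefix doubling on an integer alphabet."""
    n = len(text)
    rank = text.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r_sorted = rank[order]
        k2_sorted = key2[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (r_sorted[1:] != r_sorted[:-1]) | \
                      (k2_sorted[1:] != k2_sorted[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


class _FmHalf:
    """One direction of the index: SA, BWT occurrence table, C array."""

    def __init__(self, text: np.ndarray):
        n = len(text)
        self.sa = _suffix_array(text)
        bwt = text[(self.sa - 1) % n]
        occ = np.zeros((n + 1, 6), dtype=np.int64)
        np.cumsum(bwt[:, None] == np.arange(6), axis=0, out=occ[1:])
        self.occ = occ
        counts = occ[n]
        self.C = np.concatenate(([0], np.cumsum(counts)))[:6]


@dataclass(frozen=True)
class BiInterval:
    """A bidirectional match state: SA intervals in both index halves."""

    lo: int
    hi: int
    lo_rev: int
    hi_rev: int
    length: int

    @property
    def count(self) -> int:
        return self.hi - self.lo


class BidirectionalIndex:
    """Bidirectional FM-index over a set of named sequences.

    Sequences are concatenated with separator characters that never match a
    query base, so matches cannot straddle sequence boundaries.
    """

    def __init__(self, sequences: list[GenomeSequence]):
        if not sequences:
            raise ValueError("cannot build an index over no sequences")
        self.names = [s.name for s in sequences]
        parts = []
        starts = []
        cursor = 0
        for s in sequences:
            starts.append(cursor)
            parts.append(encode(s.seq))
            parts.append(np.array([SEP], dtype=np.uint8))
            cursor += len(s.seq) + 1
        self.text = np.concatenate(parts)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.lengths = np.asarray([len(s.seq) for s in sequences],
                                  dtype=np.int64)
        self._fwd = _FmHalf(self.text)
        self._rev = _FmHalf(self.text[::-1])

    # -- bidirectional extension --------------------------------------------

    def root(self) -> BiInterval:
        n = len(self.text)
        return BiInterval(0, n, 0, n, 0)

    def extend_left(self, itv: BiInterval, code: int) -> BiInterval | None:
        fm = self._fwd
        lo = fm.C[code] + fm.occ[itv.lo, code]
        hi = fm.C[code] + fm.occ[itv.hi, code]
        if lo >= hi:
            return None
        smaller = int((fm.occ[itv.hi, :code] - fm.occ[itv.lo, :code]).sum())
        lo_rev = itv.lo_rev + smaller
        return BiInterval(lo, hi, lo_rev, lo_rev + (hi - lo), itv.length + 1)

    def extend_right(self, itv: BiInterval, code: int) -> BiInterval | None:
        fm = self._rev
        lo_rev = fm.C[code] + fm.occ[itv.lo_rev, code]
        hi_rev = fm.C[code] + fm.occ[itv.hi_rev, code]
        if lo_rev >= hi_rev:
            return None
        smaller = int((fm.occ[itv.hi_rev, :code] -
                       fm.occ[itv.lo_rev, :code]).sum())
        lo = itv.lo + smaller
        return BiInterval(lo, lo + (hi_rev - lo_rev), lo_rev, hi_rev,
                          itv.length + 1)

    # -- exact pattern location ---------------------------------------------

    def exact_interval(self, pattern: str) -> BiInterval | None:
        itv = self.root()
        for ch in reversed(encode(pattern)):
            itv = self.extend_left(itv, int(ch))
            if itv is None:
                return None
        return itv

    def locate(self, itv: BiInterval) -> np.ndarray:
        """Global start positions of the matched pattern."""
        return np.sort(self._fwd.sa[itv.lo:itv.hi])

    def count(self, pattern: str) -> int:
        itv = self.exact_interval(pattern)
        return 0 if itv is None else itv.count

    def to_local(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map global positions to (sequence index, local position)."""
        idx = np.searchsorted(self.starts, gpos, side="right") - 1
        return idx, gpos - self.starts[idx]


# ---------------------------------------------------------------------------
# Guide search (indexed, scheme-driven) and the brute-force oracle
# ---------------------------------------------------------------------------

def _check_guide(guide: str) -> str:
    g = guide.upper()
    if len(g) == SITE_LEN:
        g = g[:PROTO_LEN]
    if len(g) != PROTO_LEN or any(c not in "ACGT" for c in g):
        raise GuideError("guide protospacer must be a 20-mer over ACGT")
    return g


def _hits_from_candidates(
    text: np.ndarray, cand: np.ndarray, pattern_enc: np.ndarray,
    pams: PamSet, max_mm: int, strand: str, scheme: SearchScheme | None,
    seed_index: int | None, names: list[str], starts: np.ndarray,
    guide_id: str,
) -> list[OffTargetHit]:
    """Verify candidate protospacer starts (global coords) against the text
    and emit hits.  When ``scheme``/``seed_index`` is given, the per-piece
    error constraints of that search are enforced (indexed path); otherwise
    only the total budget applies (brute-force path)."""
    if cand.size == 0:
        return []
    n = len(text)
    cand = cand[(cand >= 0) & (cand + PROTO_LEN <= n)]
    if cand.size == 0:
        return []
    win = text[cand[:, None] + np.arange(PROTO_LEN)]
    mmat = win != pattern_enc
    ok = ~(win == SEP).any(axis=1)
    total = mmat.sum(axis=1)
    ok &= total <= max_mm
    if scheme is not None:
        bounds = np.array([s for s, _ in scheme.parts] +
                          [scheme.pattern_length])
        piece_mm = np.add.reduceat(mmat, bounds[:-1], axis=1)
        ok &= piece_mm[:, seed_index] == 0
        if seed_index > 0:
            ok &= (piece_mm[:, :seed_index] >= 1).all(axis=1)
    # PAM: 3' of the protospacer on the plus strand, 5' (revcomp) on minus
    if strand == "+":
        pam_pos = cand + PROTO_LEN
        ok &= pam_pos + PAM_LEN <= n
        pmask = pams.mask(reverse=False)
    else:
        pam_pos = cand - PAM_LEN
        ok &= pam_pos >= 0
        pmask = pams.mask(reverse=True)
    if not ok.any():
        return []
    cand, win, mmat, pam_pos = cand[ok], win[ok], mmat[ok], pam_pos[ok]
    pam_codes = text[np.clip(pam_pos, 0, n - PAM_LEN)[:, None] +
                     np.arange(PAM_LEN)]
    pam_ok = np.zeros(len(cand), dtype=bool)
    for m in range(pmask.shape[0]):
        pam_ok |= pmask[m][np.arange(PAM_LEN), pam_codes].all(axis=1)
    if not pam_ok.any():
        return []
    cand, win, mmat, pam_codes = (cand[pam_ok], win[pam_ok], mmat[pam_ok],
                                  pam_codes[pam_ok])
    seq_idx = np.searchsorted(starts, cand, side="right") - 1
    hits = []
    for r in range(len(cand)):
        cols = np.nonzero(mmat[r])[0]
        if strand == "+":
            positions = tuple(int(c) + 1 for c in cols)
            proto = decode(win[r])
            pam = decode(pam_codes[r])
            start = int(cand[r] - starts[seq_idx[r]])
            end = start + SITE_LEN
        else:
            positions = tuple(sorted(PROTO_LEN - int(c) for c in cols))
            proto = revcomp(decode(win[r]))
            pam = revcomp(decode(pam_codes[r]))
            start = int(cand[r] - PAM_LEN - starts[seq_idx[r]])
            end = start + SITE_LEN
        hits.append(OffTargetHit(
            contig=names[seq_idx[r]], start=start, end=end, strand=strand,
            protospacer=proto, pam=pam, mismatch_positions=positions,
            n_mismatches=len(positions), guide_id=guide_id))
    return hits


def search_guide(index: BidirectionalIndex, guide: str, pams: PamSet,
                 max_mismatches: int = MAX_MM,
                 guide_id: str = "") -> list[OffTargetHit]:
    """All sites on both strands within the mismatch budget, PAM-gated."""
    if not 0 <= max_mismatches <= MAX_MM:
        raise ValueError(f"max_mismatches must lie in [0, {MAX_MM}]")
    g = _check_guide(guide)
    scheme = default_scheme(max_mismatches)
    hits: list[OffTargetHit] = []
    for strand, pattern in (("+", g), ("-", revcomp(g))):
        pattern_enc = encode(pattern)
        for i, (ps, pe) in enumerate(scheme.parts):
            itv = index.exact_interval(pattern[ps:pe])
            if itv is None:
                continue
            cand = index.locate(itv) - ps
            hits.extend(_hits_from_candidates(
                index.text, cand, pattern_enc, pams, max_mismatches,
                strand, scheme, i, index.names, index.starts, guide_id))
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def brute_force_search(sequences: list[GenomeSequence], guide: str,
                       pams: PamSet, max_mismatches: int = MAX_MM,
                       guide_id: str = "") -> list[OffTargetHit]:
    """Sliding-window Hamming scan of both strands; the search oracle."""
    g = _check_guide(guide)
    hits: list[OffTargetHit] = []
    for seq in sequences:
        if len(seq.seq) < SITE_LEN:
            continue
        text = encode(seq.seq)
        starts = np.array([0], dtype=np.int64)
        n = len(text)
        for strand, pattern in (("+", g), ("-", revcomp(g))):
            pattern_enc = encode(pattern)
            if strand == "+":
                cand = np.arange(0, n - SITE_LEN + 1)
            else:
                cand = np.arange(PAM_LEN, n - PROTO_LEN + 1)
            hits.extend(_hits_from_candidates(
                text, cand, pattern_enc, pams, max_mismatches, strand,
                None, None, [seq.name], starts, guide_id))
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Merge reference and variant hits, filter, deduplicate
# ---------------------------------------------------------------------------

def window_sequences(windows: list[VariantWindow]
                     ) -> tuple[list[GenomeSequence], dict]:
    """Flatten windows into named sequences for indexing, plus a resolver
    from sequence name back to (window, allele sequence)."""
    seqs = []
    resolver = {}
    for wi, w in enumerate(windows):
        for ai, a in enumerate(w.allele_sequences):
            name = f"__win{wi}.{ai}"
            seqs.append(GenomeSequence(name, a.seq))
            resolver[name] = (w, a)
    return seqs, resolver


def _ref_hit_absent(hit: OffTargetHit, overlapping: list[Variant]) -> bool:
    """True if the reference sequence under this hit exists on no haplotype.

    Hom-alt variants replace the reference on every haplotype; phased het
    variants on their own haplotype.  Unphased hets are conservatively
    assumed to leave the reference allele available."""
    if not overlapping:
        return False
    ploidy = max(len(v.genotype) for v in overlapping)
    for h in range(ploidy):
        if not any(
            v.is_hom_alt or (v.phased and h < len(v.genotype)
                             and v.genotype[h] == 1)
            for v in overlapping
        ):
            return False
    return True


def merge_and_filter(
    ref_hits: list[OffTargetHit],
    var_hits: list[OffTargetHit],
    windows: list[VariantWindow],
    on_targets: list[tuple[str, int, str]] | None = None,
    resolver: dict | None = None,
) -> list[OffTargetHit]:
    """Merge reference and variant-genome hits into the final hit list.

    1. reference hits whose footprint overlaps variants absent from every
       haplotype are removed;
    2. variant hits are lifted to reference coordinates and tagged with the
       overlapping variant IDs (hits not touching any variant are dropped —
       the reference scan covers them);
    3. duplicates at the same lifted locus+strand across combinations are
       collapsed (keeping the fewest-mismatch record, union of variant IDs);
    4. 0-mismatch hits at a guide's declared origin locus are removed;
       other perfect hits are flagged ``perfect_match``;
    5. hits are returned sorted by (contig, start).
    """
    if resolver is None:
        _, resolver = window_sequences(windows)
    all_variants = [v for w in windows for v in w.members]

    kept: list[OffTargetHit] = []
    for hit in ref_hits:
        overlapping = [v for v in all_variants
                       if v.contig == hit.contig
                       and v.start0 < hit.end and hit.start < v.end0]
        if not _ref_hit_absent(hit, overlapping):
            kept.append(hit)

    lifted: dict[tuple, OffTargetHit] = {}
    for hit in var_hits:
        window, allele = resolver[hit.contig]
        offs = allele.offsets
        lift_start = int(offs[hit.start])
        last = min(hit.end, len(offs)) - 1
        lift_end = int(offs[last]) + 1
        exact = (lift_end - lift_start) == (hit.end - hit.start)
        ids = tuple(v.vcf_line_id for v in allele.variants
                    if v.start0 < lift_end and lift_start < v.end0)
        if not ids:
            continue
        flags = hit.flags if exact else hit.flags + ("lifted_inexact",)
        new = replace(hit, contig=window.contig, start=lift_start,
                      end=lift_end, source="variant", variant_ids=ids,
                      flags=flags)
        key = (new.contig, new.start, new.strand)
        old = lifted.get(key)
        if old is None or new.n_mismatches < old.n_mismatches:
            merged_ids = tuple(sorted(set(ids) |
                                      set(old.variant_ids if old else ())))
            lifted[key] = replace(new, variant_ids=merged_ids)
        else:
            lifted[key] = replace(old, variant_ids=tuple(
                sorted(set(old.variant_ids) | set(ids))))
    kept.extend(lifted.values())

    origin = set(on_targets or [])
    final = []
    for hit in kept:
        if hit.n_mismatches == 0:
            if (hit.contig, hit.start, hit.strand) in origin:
                continue
            hit = replace(hit, flags=hit.flags + ("perfect_match",))
        final.append(hit)
    final.sort(key=lambda h: (h.contig, h.start, h.strand))
    return final


# ---------------------------------------------------------------------------
# BED6+ output
# ---------------------------------------------------------------------------

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand",
               "sequence", "n_mismatches", "mismatch_positions", "source",
               "variant_ids")


def write_bed(hits: list[OffTargetHit], path,
              score_name: str | None = None) -> None:
    """BED6 plus sequence/mismatch/provenance columns.  The BED score is the
    chosen score scaled to 0-1000 (0 when unscored); full-precision scores
    stay in downstream reports."""
    with open(path, "w") as fh:
        for h in hits:
            raw = h.scores.get(score_name, 0.0) if score_name else 0.0
            score = int(min(1000, max(0, round(1000 * raw))))
            mm = ";".join(str(p) for p in h.mismatch_positions) or "."
            vids = ";".join(h.variant_ids) or "."
            fh.write("\t".join(map(str, (
                h.contig, h.start, h.end, h.guide_id or "guide", score,
                h.strand, h.protospacer + h.pam, h.n_mismatches, mm,
                h.source, vids))) + "\n")
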