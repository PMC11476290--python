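"""IsomiR calling: alignment, per-read decomposition, collapsing, naming.

A trimmed read is aligned to the toy genome, assigned to a miRNA locus,
and decomposed relative to that locus's canonical mature miRNA into

* a 5' shift (negative = extension into the precursor, positive = trimming),
* a templated 3' end offset (|offset| <= 2),
* a non-templated 3' addition (NTA): the maximal 3' suffix that does not
  match the genomic continuation (capped at 3 nt), and
* internal substitutions (reads with two or more are discarded).

Reads are then collapsed into four type-specific isomiR identities.  For
each type, positions irrelevant to that type are ignored: 5' isomiRs
ignore all 3' variation, NTA isomiRs ignore 5' variation, and A-to-I
edited isomiRs ignore the final two bases of each read (a read whose only
substitution lies in its final two bases counts as unedited).
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

__all__ = [
    "MiRNALocus",
    "ReadAnnotation",
    "IsomirKind",
    "IsomiRKey",
    "GenomeIndex",
    "AlignmentHit",
    "align_read",
    "annotate_read",
    "collapse",
    "counterpart_counts",
    "name_isomir",
    "parse_name",
    "quantify",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SEED_RANGE = range(1, 8)  # 0-based positions 1-7 == nucleotides 2-8


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNALocus:
    """A miRNA hairpin embedded in the genome with its mature product.

    Genomic intervals are 0-based half-open on the forward strand;
    ``hairpin_seq``/``mature_seq`` are stored in mature-sense (5'->3')
    orientation, i.e. reverse-complemented for minus-strand loci.
    """

    mirna_name: str
    contig: str
    strand: str
    hairpin_start: int
    hairpin_end: int
    mature_start: int
    mature_end: int
    hairpin_seq: str
    mature_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.mirna_name}: bad strand {self.strand!r}")
        if not (self.hairpin_start <= self.mature_start < self.mature_end <= self.hairpin_end):
            raise ValueError(f"{self.mirna_name}: mature interval not inside hairpin")

    @property
    def mature_len(self) -> int:
        return self.mature_end - self.mature_start

    def sense_mature_start(self, genome_len: int) -> int:
        """Start of the mature sequence in strand search-space coordinates.

        Plus-strand loci live in forward-genome coordinates; minus-strand
        loci in coordinates of the reverse-complemented genome.
        """
        if self.strand == "+":
            return self.mature_start
        return genome_len - self.mature_end

    def sense_hairpin_interval(self, genome_len: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.hairpin_start, self.hairpin_end
        return genome_len - self.hairpin_end, genome_len - self.hairpin_start


class IsomirKind(str, Enum):
    FIVE_PRIME = "FIVE_PRIME"
    NTA_A = "NTA_A"
    NTA_U = "NTA_U"
    NTA_C = "NTA_C"
    NTA_G = "NTA_G"
    EDIT_AI = "EDIT_AI"
    MIRNA = "MIRNA"  # family totals, not an isomiR type


NTA_KINDS = (IsomirKind.NTA_A, IsomirKind.NTA_U, IsomirKind.NTA_C, IsomirKind.NTA_G)
_DNA_TO_RNA_BASE = {"A": "A", "T": "U", "C": "C", "G": "G"}
_RNA_TO_DNA_BASE = {v: k for k, v in _DNA_TO_RNA_BASE.items()}


@dataclass(frozen=True)
class IsomiRKey:
    """Collapsed identity of one isomiR of one type.

    coords:
      FIVE_PRIME -> (five_prime_shift,)
      NTA_*      -> (tail position 1 or 2 relative to the mature 3' end,)
      EDIT_AI    -> (five_prime_shift, edited position in isomiR coordinates)
    """

    mirna_name: str
    kind: IsomirKind
    coords: tuple[int, ...]

    @property
    def name(self) -> str:
        return name_isomir(self)


@dataclass(frozen=True)
class ReadAnnotation:
    """Decomposition of one read relative to its miRNA locus."""

    mirna_name: str
    five_prime_shift: int
    three_prime_shift: int
    nta: str
    substitutions: tuple[tuple[int, str, str], ...]  # (isomiR pos, ref, read)
    length: int  # full isomiR length including any NTA


@dataclass(frozen=True)
class AlignmentHit:
    strand: str
    pos: int  # start in strand search-space coordinates
    mismatches: int  # internal mismatches within the templated prefix
    overhang: int  # trailing non-templated bases (0-3)
    locus: Optional[MiRNALocus]


class GenomeIndex:
    """Exhaustive short-read search over a small genome.

    Candidate positions come from two 8-mer seeds (a pigeonhole split of
    the first sixteen bases: any alignment with <=1 internal mismatch
    leaves at least one seed exact); candidates are then verified
    allowing one internal mismatch plus a trailing overhang of up to
    three non-templated bases.  Both strands are searched.
    """

    K = 8
    K_SHORT = 7  # for 15-nt reads, where two disjoint 8-mers do not fit
    MAX_OVERHANG = 3
    MAX_MISMATCH = 1

    def __init__(self, genome: str, loci: Sequence[MiRNALocus] = ()):
        self.genome = genome
        self.genome_rc = revcomp(genome)
        self._index = {
            "+": {k: self._build(self.genome, k) for k in (self.K, self.K_SHORT)},
            "-": {k: self._build(self.genome_rc, k) for k in (self.K, self.K_SHORT)},
        }
        self.loci = list(loci)
        self._locus_lookup: dict[str, list[tuple[int, int, MiRNALocus]]] = {"+": [], "-": []}
        g = len(genome)
        for locus in self.loci:
            lo, hi = locus.sense_hairpin_interval(g)
            self._locus_lookup[locus.strand].append((lo, hi, locus))

    @staticmethod
    def _build(seq: str, k: int) -> dict[str, list[int]]:
        idx: dict[str, list[int]] = defaultdict(list)
        for i in range(len(seq) - k + 1):
            idx[seq[i : i + k]].append(i)
        return dict(idx)

    def _locus_at(self, strand: str, start: int, end: int) -> Optional[MiRNALocus]:
        for lo, hi, locus in self._locus_lookup[strand]:
            if start >= lo and end <= hi:
                return locus
        return None

    def search(self, seq: str) -> list[AlignmentHit]:
        if len(seq) < 2 * self.K_SHORT:
            raise ValueError(f"read too short to align: {len(seq)} nt")
        k = self.K if len(seq) >= 2 * self.K else self.K_SHORT
        hits: list[AlignmentHit] = []
        for strand in "+-":
            ref = self.genome if strand == "+" else self.genome_rc
            index = self._index[strand][k]
            candidates = set()
            for off in (0, k):
                for p in index.get(seq[off : off + k], ()):
                    if p - off >= 0:
                        candidates.add(p - off)
            for p in candidates:
                hit = self._verify(seq, ref, p, strand)
                if hit is not None:
                    hits.append(hit)
        hits.sort(key=lambda h: (h.mismatches, h.overhang, h.strand, h.pos))
        return hits

    def _verify(self, seq: str, ref: str, p: int, strand: str) -> Optional[AlignmentHit]:
        n = len(seq)
        if p + n > len(ref):
            return None
        window = ref[p : p + n]
        diffs = [i for i in range(n) if seq[i] != window[i]]
        overhang = 0
        while diffs and diffs[-1] == n - 1 - overhang and overhang < self.MAX_OVERHANG:
            diffs.pop()
            overhang += 1
        if len(diffs) > self.MAX_MISMATCH:
            return None
        templated = n - overhang
        if templated < self.K:
            return None
        locus = self._locus_at(strand, p, p + templated)
        return AlignmentHit(strand, p, len(diffs), overhang, locus)


def align_read(seq: str, index: GenomeIndex) -> list[AlignmentHit]:
    """All genomic matches of ``seq`` (<=1 internal mismatch, <=3 nt
    3' overhang), best first."""
    return index.search(seq)


def annotate_read(
    seq: str,
    hit: AlignmentHit,
    genome_len: int,
    max_three_prime_shift: int = 2,
    max_five_prime_shift: int = 5,
) -> Optional[ReadAnnotation]:
    """Decompose an aligned read; returns None when the read is discarded
    (>=2 substitutions, 3' end farther than 2 nt from the mature end, or a
    5' shift outside the hairpin's plausible window)."""
    locus = hit.locus
    if locus is None:
        return None
    n = len(seq)
    templated = n - hit.overhang
    sense_mstart = locus.sense_mature_start(genome_len)
    shift5 = hit.pos - sense_mstart
    shift3 = (hit.pos + templated) - (sense_mstart + locus.mature_len)
    if abs(shift5) > max_five_prime_shift:
        return None
    if abs(shift3) > max_three_prime_shift:
        return None
    ref = locus.hairpin_seq
    hp_lo, _ = locus.sense_hairpin_interval(genome_len)
    subs = []
    for i in range(templated):
        ref_base = ref[hit.pos - hp_lo + i]
        if seq[i] != ref_base:
            subs.append((i, ref_base, seq[i]))
    if len(subs) >= 2:
        return None
    return ReadAnnotation(
        mirna_name=locus.mirna_name,
        five_prime_shift=shift5,
        three_prime_shift=shift3,
        nta=seq[templated:],
        substitutions=tuple(subs),
        length=n,
    )


def _is_homopolymer(tail: str) -> bool:
    return len(tail) > 0 and tail == tail[0] * len(tail)


def _effective_substitutions(ann: ReadAnnotation) -> tuple[tuple[int, str, str], ...]:
    """Substitutions outside the read's final two bases (the editing
    convention: trailing-base substitutions are ignored)."""
    return tuple(s for s in ann.substitutions if s[0] < ann.length - 2)


def keys_for_annotation(ann: ReadAnnotation) -> list[IsomiRKey]:
    """Type-specific isomiR identities one read contributes to.

    A single read may contribute to several views, e.g. a 5'-shifted read
    with an adenine tail counts toward both a FIVE_PRIME key and an NTA_A
    key.
    """
    keys: list[IsomiRKey] = []
    if ann.five_prime_shift != 0:
        keys.append(IsomiRKey(ann.mirna_name, IsomirKind.FIVE_PRIME, (ann.five_prime_shift,)))
    if _is_homopolymer(ann.nta) and len(ann.nta) <= 2:
        tail_pos = ann.three_prime_shift + len(ann.nta)
        if tail_pos in (1, 2):
            base = _DNA_TO_RNA_BASE.get(ann.nta[0])
            if base is not None:
                keys.append(IsomiRKey(ann.mirna_name, IsomirKind[f"NTA_{base}"], (tail_pos,)))
    eff = _effective_substitutions(ann)
    if len(eff) == 1:
        pos, ref, alt = eff[0]
        if ref == "A" and alt == "G":
            keys.append(IsomiRKey(ann.mirna_name, IsomirKind.EDIT_AI, (ann.five_prime_shift, pos)))
    return keys


def collapse(
    annotations: Iterable[tuple[ReadAnnotation, int]],
    kind: IsomirKind | None = None,
) -> dict[IsomiRKey, int]:
    """Collapse per-read annotations into type-specific isomiR counts.

    ``kind=None`` collapses all four types at once; otherwise only keys of
    the requested type are returned.
    """
    counts: Counter[IsomiRKey] = Counter()
    for ann, c in annotations:
        for key in keys_for_annotation(ann):
            if kind is None or key.kind == kind:
                counts[key] += c
    return dict(counts)


def counterpart_counts(
    annotations: Iterable[tuple[ReadAnnotation, int]],
    keys: Iterable[IsomiRKey],
) -> dict[IsomiRKey, int]:
    """Counts of 'otherwise identical' reads lacking each key's event.

    These are the binomial-test denominators: for a 5' isomiR, reads with
    the canonical 5' end; for an NTA isomiR, reads of the same miRNA with
    no non-templated tail; for an edited isomiR, reads with the same 5'
    shift that are unedited at the site (substitutions in the final two
    bases ignored).
    """
    anns = list(annotations)
    canonical5: Counter[str] = Counter()
    untailed: Counter[str] = Counter()
    by_shift: Counter[tuple[str, int]] = Counter()
    edited: Counter[tuple[str, int, int]] = Counter()
    for ann, c in anns:
        if ann.five_prime_shift == 0:
            canonical5[ann.mirna_name] += c
        if ann.nta == "":
            untailed[ann.mirna_name] += c
        by_shift[(ann.mirna_name, ann.five_prime_shift)] += c
        eff = _effective_substitutions(ann)
        if len(eff) == 1:
            pos, ref, alt = eff[0]
            if ref == "A" and alt == "G":
                edited[(ann.mirna_name, ann.five_prime_shift, pos)] += c
    out: dict[IsomiRKey, int] = {}
    for key in keys:
        if key.kind == IsomirKind.FIVE_PRIME:
            out[key] = canonical5[key.mirna_name]
        elif key.kind in NTA_KINDS:
            out[key] = untailed[key.mirna_name]
        elif key.kind == IsomirKind.EDIT_AI:
            shift, pos = key.coords
            total = by_shift[(key.mirna_name, shift)]
            out[key] = total - edited[(key.mirna_name, shift, pos)]
        else:
            raise ValueError(f"no counterpart rule for {key.kind}")
    return out


def name_isomir(key: IsomiRKey) -> str:
    """Canonical isomiR name, e.g. ``hsa-miR-200b-3p 0 4 AI``,
    ``hsa-miR-140-3p 1``, ``hsa-miR-99a-5p 1A``."""
    if key.kind == IsomirKind.EDIT_AI:
        shift, pos = key.coords
        return f"{key.mirna_name} {shift} {pos} AI"
    if key.kind == IsomirKind.FIVE_PRIME:
        return f"{key.mirna_name} {key.coords[0]}"
    if key.kind in NTA_KINDS:
        base = key.kind.value.split("_")[1]
        return f"{key.mirna_name} {key.coords[0]}{base}"
    if key.kind == IsomirKind.MIRNA:
        return key.mirna_name
    raise ValueError(f"cannot name {key.kind}")


_NTA_RE = re.compile(r"^([12])([AUCG])$")


def parse_name(name: str) -> IsomiRKey:
    """Inverse of :func:`name_isomir` (round-trips on all generated keys)."""
    parts = name.split(" ")
    if len(parts) == 4 and parts[3] == "AI":
        return IsomiRKey(parts[0], IsomirKind.EDIT_AI, (int(parts[1]), int(parts[2])))
    if len(parts) == 2:
        m = _NTA_RE.match(parts[1])
        if m:
            return IsomiRKey(parts[0], IsomirKind[f"NTA_{m.group(2)}"], (int(m.group(1)),))
        return IsomiRKey(parts[0], IsomirKind.FIVE_PRIME, (int(parts[1]),))
    if len(parts) == 1:
        return IsomiRKey(parts[0], IsomirKind.MIRNA, ())
    raise ValueError(f"unparseable isomiR name: {name!r}")


def quantify(counts: dict, total_mapped: int) -> dict:
    """Reads-per-million for each keyed count.

    ``total_mapped`` is the number of miRNA-mapped reads in the sample;
    a sample with zero mapped reads must be rejected upstream.
    """
    if total_mapped <= 0:
        raise ValueError("sample has no miRNA-mapped reads")
    return {k: c * 1e6 / total_mapped for k, c in counts.items()}
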