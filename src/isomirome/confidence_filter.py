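"""Separating genuine isomiRs from sequencing artifacts.

An observed isomiR can arise from a real modification or from a
sequencing error on reads of a similar sequence.  The error hypothesis
is tested per sample with a binomial tail: the isomiR's read count k and
the count of otherwise identical reads lacking its characteristic event
are combined into n trials, and p = P(X >= k) for X ~ Binomial(n, e)
where e is the baseline error rate.  Substitution error rates are the
greater of the Phred-25 expectation (0.32%) and the rate of the same
substitution at the same read position observed on the same sequencing
plate; 5' shifts and non-templated tails use a conservative 2% floor.
The hypothesis is rejected (isomiR believed real) at BH-FDR < 0.05 with
at least three supporting reads.

Beyond the error test, isomiRs are discarded when their characteristic
variant matches a SNP/somatic blacklist, when their most highly
expressed sequence cross-maps to another genomic site at least as well
as to its home hairpin (with a dedicated re-check for tRNA CCA tails),
and a catalog-level "high-confidence" flag requires expression in at
least one sample group in at least two of the three cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .isomir_annotation import (
    NTA_KINDS,
    AlignmentHit,
    GenomeIndex,
    IsomirKind,
    IsomiRKey,
)
from .read_prep import phred_error_rate

__all__ = [
    "SUBSTITUTION_FLOOR",
    "NTA_FIVE_PRIME_RATE",
    "ErrorRateModel",
    "estimate_error_rates",
    "binomial_error_test",
    "reject_error_hypothesis",
    "expressed_in_group",
    "blacklist_filter",
    "cross_map_filter",
    "high_confidence",
]

SUBSTITUTION_FLOOR = phred_error_rate(25)  # 0.0032 (0.32%)
NTA_FIVE_PRIME_RATE = 0.02  # conservative constant for 5' shifts and tails


@dataclass
class ErrorRateModel:
    """Plate x read-position x substitution-type baseline error rates.

    ``observed`` maps (plate, position, "X>Y") to the mismatch fraction
    estimated from reads matching canonical sequences; queries return
    max(floor, observed), falling back to the floor where a stratum has
    no coverage.
    """

    observed: dict = field(default_factory=dict)
    plates: frozenset = frozenset()
    floor: float = SUBSTITUTION_FLOOR
    nta_five_prime_rate: float = NTA_FIVE_PRIME_RATE

    def substitution_rate(self, plate: str, position: int, subtype: str) -> float:
        if self.plates and plate not in self.plates:
            raise KeyError(f"unknown plate {plate!r}")
        return max(self.floor, self.observed.get((plate, position, subtype), 0.0))

    def event_rate(self, kind: IsomirKind, plate: str, position: int = 0,
                   subtype: str = "") -> float:
        if kind == IsomirKind.EDIT_AI:
            return self.substitution_rate(plate, position, subtype or "A>G")
        return self.nta_five_prime_rate


def estimate_error_rates(
    mismatches: Mapping[tuple, int],
    coverage: Mapping[tuple, int],
    floor: float = SUBSTITUTION_FLOOR,
) -> ErrorRateModel:
    """Build the error model from per-plate tallies.

    ``mismatches[(plate, pos, "X>Y")]`` counts reads carrying that
    substitution; ``coverage[(plate, pos)]`` counts all canonical-
    sequence reads covering the position.  Only reads with at most one
    substitution that map to canonical sequences should be tallied, to
    avoid circularity with the isomiRs under test.
    """
    observed = {}
    for (plate, pos, subtype), k in mismatches.items():
        n = coverage.get((plate, pos), 0)
        if n > 0:
            observed[(plate, pos, subtype)] = k / (n)
    plates = frozenset(p for p, _, _ in mismatches) | frozenset(p for p, _ in coverage)
    return ErrorRateModel(observed=observed, plates=plates, floor=floor)


def binomial_error_test(k_isomir: int, k_counterpart: int, e: float) -> float:
    """Upper-tail binomial probability that all k isomiR reads are errors.

    p = P(X >= k_isomir) with X ~ Binomial(k_isomir + k_counterpart, e).
    Zero observed reads (n = 0) give p = 1.
    """
    if k_isomir < 0 or k_counterpart < 0:
        raise ValueError("read counts must be non-negative")
    if not (0 < e < 1):
        raise ValueError(f"error rate must be in (0, 1), got {e}")
    n = k_isomir + k_counterpart
    if n == 0 or k_isomir == 0:
        return 1.0
    return float(stats.binom.sf(k_isomir - 1, n, e))


def reject_error_hypothesis(
    pvalues: Sequence[float],
    read_counts: Sequence[int],
    alpha: float = 0.05,
    min_reads: int = 3,
) -> np.ndarray:
    """BH-adjust the sample's candidate p-values and require >= min_reads.

    The BH family is all candidate isomiRs of one type within one
    sample.  Returns a boolean array aligned with the inputs.
    """
    p = np.asarray(pvalues, dtype=float)
    counts = np.asarray(read_counts)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if p.size != counts.size:
        raise ValueError("p-values and read counts must align")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return (p_adj < alpha) & (counts >= min_reads)


def expressed_in_group(
    rpm_pass: Sequence[bool],
    error_pass: Sequence[bool] | None,
    min_fraction: float = 0.10,
) -> bool:
    """Expression call for one (isomiR, cohort, group).

    Both criteria — (a) >= 1 RPM and (b) surviving the error test — must
    each hold in at least ``min_fraction`` of the group's samples
    (independently).  Pass ``error_pass=None`` for miRNAs, which use
    criterion (a) only.
    """
    rpm_pass = list(rpm_pass)
    if not rpm_pass:
        raise ValueError("group has no retained samples")
    n = len(rpm_pass)
    frac_a = sum(rpm_pass) / n
    if frac_a < min_fraction - 1e-12:
        return False
    if error_pass is None:
        return True
    error_pass = list(error_pass)
    if len(error_pass) != n:
        raise ValueError("criterion vectors must align")
    return sum(error_pass) / n >= min_fraction - 1e-12


def blacklist_filter(key: IsomiRKey, blacklist: Iterable, mature_len: int = 22) -> bool:
    """True (keep) unless the key's characteristic substitution or tail
    matches a blacklist entry (mature-coordinate offset + alt base).

    Edited keys are checked at mature offset = isomiR position + 5'
    shift with alt G; tail keys at the templated continuation position
    with alt = tail base; 5' keys carry no substitution and always pass.
    """
    entries = {(b.mirna_name, b.offset, b.alt) for b in blacklist}
    if key.kind == IsomirKind.EDIT_AI:
        shift, pos = key.coords
        return (key.mirna_name, pos + shift, "G") not in entries
    if key.kind in NTA_KINDS:
        base = {"NTA_A": "A", "NTA_U": "T", "NTA_C": "C", "NTA_G": "G"}[key.kind.value]
        offset = mature_len - 1 + key.coords[0]
        return (key.mirna_name, offset, base) not in entries
    return True


def cross_map_filter(
    key: IsomiRKey,
    top_sequence: str,
    index: GenomeIndex,
    trna_regions: Sequence[tuple] = (),
) -> bool:
    """True (keep) unless the isomiR's most highly expressed sequence
    maps elsewhere in the genome as well as it maps to its own hairpin.

    "As well" means an equal-or-lower internal mismatch count; on a
    mismatch tie the hit with the shorter non-templated overhang wins,
    with ties broken in favor of discarding (conservative).  Sequences
    ending in CCA are additionally re-searched after removing the CCA
    and discarded if the trimmed sequence maps into a tRNA region.
    """
    hits = index.search(top_sequence)
    home = [h for h in hits if h.locus is not None and h.locus.mirna_name == key.mirna_name]
    if not home:
        return False  # cannot even place it at its own locus
    best = min(home, key=lambda h: (h.mismatches, h.overhang))
    for h in hits:
        if h.locus is not None and h.locus.mirna_name == key.mirna_name:
            continue
        if h.mismatches < best.mismatches:
            return False
        if h.mismatches == best.mismatches and h.overhang <= best.overhang:
            return False
    if top_sequence.endswith("CCA") and trna_regions:
        trimmed = top_sequence[:-3]
        if len(trimmed) >= 2 * GenomeIndex.K_SHORT:
            for h in index.search(trimmed):
                if h.mismatches == 0 and _hit_in_trna(h, index, len(trimmed), trna_regions):
                    return False
    return True


def _hit_in_trna(hit: AlignmentHit, index: GenomeIndex, length: int,
                 trna_regions: Sequence[tuple]) -> bool:
    g = len(index.genome)
    if hit.strand == "+":
        start, end = hit.pos, hit.pos + length
    else:
        start, end = g - hit.pos - length, g - hit.pos
    for t_start, t_end, *_ in trna_regions:
        if start < t_end and end > t_start:
            return True
    return False


def high_confidence(expressed_by_cohort: Mapping[str, Mapping[str, bool]],
                    min_cohorts: int = 2) -> bool:
    """True iff the isomiR/miRNA is expressed in >= min_cohorts cohorts
    (in at least one sample group per counted cohort)."""
    n = sum(any(groups.values()) for groups in expressed_by_cohort.values() if groups)
    return n >= min_cohorts
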