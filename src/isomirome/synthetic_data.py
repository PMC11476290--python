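"""Synthetic small-RNA cohorts with planted isomiR ground truth.

This module builds a toy genome carrying miRNA hairpins, a tRNA, a
duplicated ("decoy") locus and a SNP-like blacklist site, and simulates
three cohorts of paired non-malignant (ANL) / tumor (LUAD) libraries in
which A-to-I editing, 3' adenylation/uridylation, and 5'-shift
frequencies are known exactly per sample.  Tumor samples apply
configurable group effects (editing and adenylation down, uridylation
up by default), per-sample editing rates are coupled to simulated
editing-enzyme (ADAR / ADARB1 analogue) expression through shared latent
factors, plates carry distinct substitution error rates, and overall
survival is coupled to the editing latent so that every downstream
statistic has a recoverable planted signal.

The generator is deterministic given a seed: identical seeds yield
byte-identical FASTQ output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .isomir_annotation import MiRNALocus, revcomp
from .read_prep import ReadRecord

__all__ = [
    "LocusConfig",
    "CohortConfig",
    "SimulationConfig",
    "ReferenceBundle",
    "TruthProfile",
    "LocusTruth",
    "CohortData",
    "default_config",
    "null_config",
    "separable_config",
    "small_config",
    "make_reference",
    "simulate_sample",
    "simulate_cohorts",
]

ADAPTER_ILLUMINA = "ATCTCGTATGCCGTCTTCTGCTTGT"
ADAPTER_EWU = "TGGAATTCTCGGGTGCCAAGG"

_BASES = np.frombuffer(b"ACGT", dtype="S1")
Q_HI = 30
Q_LOW = 20


# ---------------------------------------------------------------------------
# configuration


@dataclass
class LocusConfig:
    """Simulation parameters for one miRNA locus.

    Frequencies are baseline (ANL) per-read event probabilities;
    ``*_group_effect`` values are additive shifts applied in LUAD
    samples.  ``edit_coupling`` names the enzyme latent factor ("ADAR" or
    "ADARB1") that multiplicatively modulates the per-sample editing
    frequency.
    """

    name: str
    abundance: float = 1.0
    mature_len: int = 22
    strand: str = "+"
    position: Optional[int] = None  # explicit hairpin start, else auto-placed
    edit_site: Optional[int] = None  # mature-coordinate offset of the A
    edit_freq: float = 0.0
    edit_group_effect: float = 0.0
    edit_adj5: str = "T"  # base immediately 5' of the edited A (T == U)
    edit_coupling: Optional[str] = None
    nta_freqs: dict = field(default_factory=dict)  # DNA base -> tail prob
    nta_group_effects: dict = field(default_factory=dict)
    shift5_freqs: dict = field(default_factory=dict)  # shift -> prob
    shift5_group_effects: dict = field(default_factory=dict)
    snp_site: Optional[tuple[int, str]] = None  # (mature offset, alt base)
    snp_freq: float = 0.0
    decoy_copies: int = 1

    def validate(self) -> None:
        if sum(self.shift5_freqs.values()) > 1:
            raise ValueError(f"{self.name}: 5'-shift frequencies sum to > 1")
        if sum(self.nta_freqs.values()) > 1:
            raise ValueError(f"{self.name}: NTA frequencies sum to > 1")
        for f in [self.edit_freq, self.snp_freq, *self.nta_freqs.values(), *self.shift5_freqs.values()]:
            if not 0 <= f <= 1:
                raise ValueError(f"{self.name}: frequency {f} outside [0, 1]")


@dataclass
class CohortConfig:
    name: str
    n_pairs: int
    adapter: str
    plates: list = field(default_factory=lambda: [("P1", 0.002), ("P2", 0.004)])
    paired: bool = True
    extra_unpaired_luad: int = 0

    def validate(self) -> None:
        if self.paired and self.extra_unpaired_luad:
            raise ValueError(
                f"cohort {self.name}: unpaired LUAD patients in a paired cohort"
            )


@dataclass
class SimulationConfig:
    loci: list = field(default_factory=list)
    cohorts: list = field(default_factory=list)
    genome_length: int = 50_000
    hairpin_len: int = 70
    mature_offset: int = 20  # mature start within the hairpin (sense)
    n_trna: int = 1
    n_reads: int = 50_000
    low_q_read_frac: float = 0.002
    shift3_freqs: dict = field(default_factory=lambda: {-2: 0.04, -1: 0.10, 0: 0.72, 1: 0.10, 2: 0.04})
    tail_len2_frac: float = 0.2  # fraction of A/U tails that are 2 nt
    sigma_patient: float = 0.12  # patient-level lognormal sd on frequencies
    sigma_sample: float = 0.08  # sample-level lognormal sd
    enzyme_coupling: float = 0.35  # log-scale slope of editing on enzyme latent
    survival_beta: float = 0.8  # log-hazard per unit editing latent (negative effect)
    survival_median_months: float = 36.0
    stage_iii_frac: float = 0.2
    blacklist_extra: list = field(default_factory=list)
    seed_note: str = ""

    def validate(self) -> None:
        if len(self.loci) < 8:
            raise ValueError("config must name at least 8 miRNA loci")
        for lc in self.loci:
            lc.validate()
        for cc in self.cohorts:
            cc.validate()
        if abs(sum(self.shift3_freqs.values()) - 1) > 1e-9:
            raise ValueError("3'-shift frequencies must sum to 1")


def _default_loci() -> list[LocusConfig]:
    """Twelve loci spanning all planted event classes.

    Editing sites cover seed (positions 1-7) and non-seed positions and
    are mostly preceded by U, mirroring ADAR-family sequence preference.
    LUAD effects: ADARB1-coupled editing and a subset of adenylation
    sites decrease, uridylation and ADAR-coupled editing increase.
    """
    return [
        LocusConfig("syn-miR-11-5p", abundance=30, edit_site=4, edit_freq=0.16,
                    edit_group_effect=-0.05, edit_coupling="ADARB1",
                    nta_freqs={"A": 0.10, "T": 0.06, "C": 0.004, "G": 0.003},
                    nta_group_effects={"A": -0.04, "T": 0.03},
                    shift5_freqs={1: 0.05}),
        LocusConfig("syn-miR-12-3p", abundance=22, edit_site=2, edit_freq=0.14,
                    edit_group_effect=-0.05, edit_coupling="ADARB1",
                    nta_freqs={"A": 0.12, "T": 0.05, "C": 0.004, "G": 0.003},
                    nta_group_effects={"A": -0.04},
                    shift5_freqs={-1: 0.06}, shift5_group_effects={-1: 0.02}),
        LocusConfig("syn-miR-13-5p", abundance=16, edit_site=5, edit_freq=0.10,
                    edit_group_effect=0.04, edit_coupling="ADAR",
                    nta_freqs={"A": 0.08, "T": 0.07},
                    nta_group_effects={"T": 0.03}),
        LocusConfig("syn-miR-14-3p", abundance=12, edit_site=3, edit_freq=0.18,
                    edit_group_effect=-0.05, edit_coupling="ADARB1",
                    nta_freqs={"A": 0.09, "T": 0.04},
                    nta_group_effects={"A": -0.04}),
        LocusConfig("syn-miR-15-5p", abundance=9, edit_site=0, edit_freq=0.12,
                    edit_group_effect=-0.04, edit_coupling="ADARB1", edit_adj5="A",
                    nta_freqs={"A": 0.07, "T": 0.08},
                    nta_group_effects={"T": 0.04},
                    shift5_freqs={-1: 0.08}),
        LocusConfig("syn-miR-16-3p", abundance=7, edit_site=6, edit_freq=0.10,
                    nta_freqs={"A": 0.10, "T": 0.05}),
        LocusConfig("syn-miR-17-5p", abundance=5, edit_site=16, edit_freq=0.12,
                    edit_group_effect=0.03, edit_coupling="ADAR", edit_adj5="C",
                    nta_freqs={"A": 0.06, "T": 0.06},
                    nta_group_effects={"A": -0.03}),
        LocusConfig("syn-miR-18-3p", abundance=4, edit_site=1, edit_freq=0.15,
                    edit_group_effect=-0.05, edit_coupling="ADARB1",
                    nta_freqs={"A": 0.08, "T": 0.05},
                    nta_group_effects={"T": 0.025},
                    shift5_freqs={2: 0.04}),
        LocusConfig("syn-miR-19-5p", abundance=3, strand="-",
                    nta_freqs={"A": 0.12, "T": 0.06},
                    nta_group_effects={"A": -0.05},
                    shift5_freqs={1: 0.07}, shift5_group_effects={1: 0.03}),
        LocusConfig("syn-miR-20-3p", abundance=2.5,
                    nta_freqs={"A": 0.07, "T": 0.10},
                    nta_group_effects={"T": 0.05},
                    shift5_freqs={-2: 0.05}),
        LocusConfig("syn-miR-dup-5p", abundance=2, decoy_copies=2,
                    nta_freqs={"A": 0.10, "T": 0.04}),
        LocusConfig("syn-miR-22-3p", abundance=2, edit_site=4, edit_freq=0.13,
                    edit_group_effect=-0.05, edit_coupling="ADARB1",
                    snp_site=(8, "G"), snp_freq=0.5),
    ]


def default_config() -> SimulationConfig:
    """The benchmark study design: three cohorts of paired ANL/LUAD
    libraries (the middle cohort largest, the third using a different 3'
    adapter), two plates per cohort with distinct error rates."""
    return SimulationConfig(
        loci=_default_loci(),
        cohorts=[
            CohortConfig("BCCA", 18, ADAPTER_ILLUMINA, [("B1", 0.002), ("B2", 0.004)]),
            CohortConfig("TCGA", 24, ADAPTER_ILLUMINA, [("T1", 0.002), ("T2", 0.005)]),
            CohortConfig("EWU", 18, ADAPTER_EWU, [("E1", 0.003), ("E2", 0.004)]),
        ],
    )


def null_config() -> SimulationConfig:
    """Default design with every LUAD group effect removed (paired truth
    frequencies identical between groups up to sampling noise)."""
    cfg = default_config()
    for lc in cfg.loci:
        lc.edit_group_effect = 0.0
        lc.nta_group_effects = {}
        lc.shift5_group_effects = {}
    cfg.survival_beta = 0.0
    return cfg


def separable_config() -> SimulationConfig:
    """The strong-effect regime for biomarker evaluation: doubled LUAD
    group effects and weaker enzyme-latent modulation, so the planted
    group signal dominates within-group biological variation."""
    cfg = default_config()
    for lc in cfg.loci:
        lc.edit_group_effect *= 2
        lc.nta_group_effects = {b: 2 * v for b, v in lc.nta_group_effects.items()}
        lc.shift5_group_effects = {s: 2 * v for s, v in lc.shift5_group_effects.items()}
    cfg.enzyme_coupling = 0.15
    return cfg


def small_config(n_pairs: int = 6, n_reads: int = 4000) -> SimulationConfig:
    """Scaled-down design for quick exercises and unit tests."""
    cfg = default_config()
    for cc in cfg.cohorts:
        cc.n_pairs = n_pairs
    cfg.n_reads = n_reads
    return cfg


def config_from_yaml(path) -> SimulationConfig:
    """Load a simulation config from YAML (keys mirror the dataclasses)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = default_config()
    if not raw:
        return cfg
    for key in ("genome_length", "n_reads", "low_q_read_frac", "sigma_patient",
                "sigma_sample", "enzyme_coupling", "survival_beta", "stage_iii_frac"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "cohorts" in raw:
        cfg.cohorts = [CohortConfig(**c) for c in raw["cohorts"]]
    if "loci" in raw:
        cfg.loci = [LocusConfig(**c) for c in raw["loci"]]
    return cfg


# ---------------------------------------------------------------------------
# reference bundle


@dataclass(frozen=True)
class BlacklistEntry:
    """A known SNP / somatic variant: isomiRs whose characteristic
    substitution or tail matches it are not trustworthy modifications."""

    mirna_name: str
    offset: int  # mature-coordinate offset of the variant base
    alt: str


@dataclass
class ReferenceBundle:
    """Toy genome plus annotations: the coordinate frame for all calls."""

    genome: str
    loci: list
    trna_regions: list  # (start, end, strand)
    decoy_regions: list  # (start, end)
    blacklist: list

    def locus(self, name: str) -> MiRNALocus:
        for lc in self.loci:
            if lc.mirna_name == name:
                return lc
        raise KeyError(name)

    def write_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            fh.write(">chrS\n")
            for i in range(0, len(self.genome), 80):
                fh.write(self.genome[i : i + 80] + "\n")
        rows = [
            {
                "mirna_name": l.mirna_name, "contig": l.contig, "strand": l.strand,
                "hairpin_start": l.hairpin_start, "hairpin_end": l.hairpin_end,
                "mature_start": l.mature_start, "mature_end": l.mature_end,
            }
            for l in self.loci
        ]
        pd.DataFrame(rows).to_csv(outdir / "loci.tsv", sep="\t", index=False)
        pd.DataFrame(self.trna_regions, columns=["start", "end", "strand"]).to_csv(
            outdir / "trna.tsv", sep="\t", index=False)
        pd.DataFrame(self.decoy_regions, columns=["start", "end"]).to_csv(
            outdir / "decoys.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"mirna_name": b.mirna_name, "offset": b.offset, "alt": b.alt} for b in self.blacklist]
        ).to_csv(outdir / "blacklist.tsv", sep="\t", index=False)

    @classmethod
    def load_dir(cls, indir) -> "ReferenceBundle":
        indir = Path(indir)
        genome = "".join(
            line.strip() for line in open(indir / "genome.fa") if not line.startswith(">")
        )
        loci = []
        for _, r in pd.read_csv(indir / "loci.tsv", sep="\t").iterrows():
            hp = genome[r.hairpin_start : r.hairpin_end]
            mat = genome[r.mature_start : r.mature_end]
            if r.strand == "-":
                hp, mat = revcomp(hp), revcomp(mat)
            loci.append(MiRNALocus(r.mirna_name, r.contig, r.strand,
                                   int(r.hairpin_start), int(r.hairpin_end),
                                   int(r.mature_start), int(r.mature_end), hp, mat))
        trna = [tuple(x) for x in pd.read_csv(indir / "trna.tsv", sep="\t").itertuples(index=False)]
        decoys = [tuple(x) for x in pd.read_csv(indir / "decoys.tsv", sep="\t").itertuples(index=False)]
        bl_df = pd.read_csv(indir / "blacklist.tsv", sep="\t")
        blacklist = [BlacklistEntry(r.mirna_name, int(r.offset), r.alt) for _, r in bl_df.iterrows()]
        return cls(genome, loci, trna, decoys, blacklist)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def make_reference(config: SimulationConfig, seed: int) -> ReferenceBundle:
    """Build the toy genome with embedded hairpins, tRNA, decoy copies
    and blacklist entries.  Deterministic for a given seed; mature
    sequences are unique in the genome except for designated decoys."""
    config.validate()
    if config.n_trna < 1:
        raise ValueError("config must include at least one tRNA region")
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        bundle = _try_make_reference(config, rng)
        if bundle is not None:
            return bundle
    raise RuntimeError("could not build a reference with unique mature sequences")


def _try_make_reference(config: SimulationConfig, rng) -> Optional[ReferenceBundle]:
    g_len = config.genome_length
    genome = list(_random_seq(rng, g_len))
    n_slots = len(config.loci) + config.n_trna + 2  # + decoy and spare slot
    spacing = g_len // (n_slots + 1)
    hp_len = config.hairpin_len
    moff = config.mature_offset

    placements = []
    for i, lc in enumerate(config.loci):
        start = lc.position if lc.position is not None else (i + 1) * spacing
        placements.append((start, start + hp_len, lc))
    placements.sort(key=lambda t: t[0])
    for (s1, e1, a), (s2, e2, b) in zip(placements, placements[1:]):
        if e1 > s2:
            raise ValueError(
                f"requested hairpin intervals overlap: {a.name} [{s1},{e1}) and {b.name} [{s2},{e2})"
            )

    loci: list[MiRNALocus] = []
    mature_seqs: dict[str, str] = {}
    for li, (start, end, lc) in enumerate(placements):
        mlen = lc.mature_len
        hp_sense = list(_random_seq(rng, hp_len))
        # Fix the two bases past the mature 3' end to C/G (alternating
        # order per locus) so planted A/U tails are always non-templated
        # and C or G tails are detectable at half the loci each; a tail
        # matching its genomic continuation is indistinguishable from a
        # templated 3' extension, as in real data.
        cont = "CG" if li % 2 == 0 else "GC"
        hp_sense[moff + mlen] = cont[0]
        hp_sense[moff + mlen + 1] = cont[1]
        if lc.edit_site is not None:
            hp_sense[moff + lc.edit_site] = "A"
            hp_sense[moff + lc.edit_site - 1] = lc.edit_adj5
        if lc.snp_site is not None:
            hp_sense[moff + lc.snp_site[0]] = "A"
        hp_sense = "".join(hp_sense)
        mature = hp_sense[moff : moff + mlen]
        genomic_hp = hp_sense if lc.strand == "+" else revcomp(hp_sense)
        genome[start:end] = genomic_hp
        if lc.strand == "+":
            mstart, mend = start + moff, start + moff + mlen
        else:
            mend = end - moff
            mstart = mend - mlen
        loci.append(MiRNALocus(lc.name, "chrS", lc.strand, start, end, mstart, mend,
                               hp_sense, mature))
        mature_seqs[lc.name] = mature

    # tRNA region(s) in the slot after the hairpins.
    trna_regions = []
    for j in range(config.n_trna):
        t_start = (len(config.loci) + 1 + j) * spacing
        trna_regions.append((t_start, t_start + 72, "+"))

    # Decoy copies: duplicate the decoy mature sequence elsewhere.
    decoy_regions = []
    d_start = (len(config.loci) + config.n_trna + 1) * spacing
    for lc in config.loci:
        for copy in range(lc.decoy_copies - 1):
            mature = mature_seqs[lc.name]
            genome[d_start : d_start + len(mature)] = mature
            decoy_regions.append((d_start, d_start + len(mature)))
            d_start += len(mature) + 50

    genome = "".join(genome)
    # Verify mature uniqueness (decoys excepted).
    for lc in config.loci:
        mature = mature_seqs[lc.name]
        n_hits = _count_occurrences(genome, mature) + _count_occurrences(genome, revcomp(mature))
        if n_hits != lc.decoy_copies:
            return None

    blacklist = [
        BlacklistEntry(lc.name, lc.snp_site[0], lc.snp_site[1])
        for lc in config.loci
        if lc.snp_site is not None
    ] + [BlacklistEntry(*e) for e in config.blacklist_extra]
    return ReferenceBundle(genome, loci, trna_regions, decoy_regions, blacklist)


def _count_occurrences(hay: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


# ---------------------------------------------------------------------------
# truth profiles and per-sample simulation


@dataclass
class LocusTruth:
    """Realized per-sample event probabilities for one locus."""

    edit_freq: float = 0.0
    edit_site: Optional[int] = None
    nta_freqs: dict = field(default_factory=dict)
    shift5_freqs: dict = field(default_factory=dict)
    snp_freq: float = 0.0
    snp_site_info: Optional[tuple] = None  # (mature offset, alt base)


@dataclass
class TruthProfile:
    """Everything needed to simulate one library: locus abundance
    weights, realized event frequencies, and the plate error rate."""

    abundance: dict
    loci: dict  # locus name -> LocusTruth
    plate_error_rate: float
    low_q_read_frac: float = 0.002
    shift3_freqs: dict = field(default_factory=lambda: {0: 1.0})
    tail_len2_frac: float = 0.2

    def validate(self) -> None:
        for name, lt in self.loci.items():
            freqs = [lt.edit_freq, lt.snp_freq, *lt.nta_freqs.values(), *lt.shift5_freqs.values()]
            if any(not 0 <= f <= 1 for f in freqs):
                raise ValueError(f"{name}: frequency outside [0, 1]")
            if sum(lt.shift5_freqs.values()) > 1:
                raise ValueError(f"{name}: competing 5'-shift frequencies sum to > 1")
            if sum(lt.nta_freqs.values()) > 1:
                raise ValueError(f"{name}: NTA frequencies sum to > 1")


def simulate_sample(
    bundle: ReferenceBundle,
    profile: TruthProfile,
    n_reads: int,
    adapter: str,
    seed: int,
    sample_id: str = "S",
    config: SimulationConfig | None = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate one library.

    Each read is a (possibly 5'-shifted, edited, tail-extended) mature
    sequence followed by the full 3' adapter; per-base substitution
    errors are drawn at the profile's plate rate (at most one per read,
    applied to the insert), and a configurable fraction of reads carry a
    single base below the Phred-25 quality floor.  The returned truth
    table has one row per generating-event combination with its read
    count; counts sum to ``n_reads``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not adapter:
        raise ValueError("adapter must be non-empty")
    profile.validate()
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)

    names = sorted(profile.abundance)
    weights = np.array([profile.abundance[n] for n in names], float)
    probs = weights / weights.sum()
    per_locus = rng.multinomial(n_reads, probs)

    records: list[ReadRecord] = []
    truth_rows = []
    read_i = 0
    for name, n_l in zip(names, per_locus):
        if n_l == 0:
            continue
        locus = bundle.locus(name)
        lt: LocusTruth = profile.loci.get(name, LocusTruth())
        moff = locus.hairpin_seq.find(locus.mature_seq)
        mlen = locus.mature_len

        s5_vals = [0] + sorted(lt.shift5_freqs)
        s5_p = np.array([1 - sum(lt.shift5_freqs.values())] + [lt.shift5_freqs[s] for s in sorted(lt.shift5_freqs)])
        s5 = rng.choice(len(s5_vals), size=n_l, p=s5_p)

        s3_vals = sorted(profile.shift3_freqs)
        s3_p = np.array([profile.shift3_freqs[s] for s in s3_vals], float)
        s3 = rng.choice(len(s3_vals), size=n_l, p=s3_p / s3_p.sum())

        tail_opts = [""]
        tail_p = [1 - sum(lt.nta_freqs.values())]
        for base, f in sorted(lt.nta_freqs.items()):
            tail_opts += [base, base * 2]
            tail_p += [f * (1 - profile.tail_len2_frac), f * profile.tail_len2_frac]
        tails = rng.choice(len(tail_opts), size=n_l, p=np.array(tail_p))

        edit = (rng.random(n_l) < lt.edit_freq).astype(np.int8) if lt.edit_freq else np.zeros(n_l, np.int8)
        snp = (rng.random(n_l) < lt.snp_freq).astype(np.int8) if lt.snp_freq else np.zeros(n_l, np.int8)
        # Tailed reads use the canonical templated 3' end so the tail is
        # unambiguously non-templated.
        s3 = np.where(tails > 0, s3_vals.index(0), s3)

        combos = np.stack([s5, s3, tails, edit, snp], axis=1)
        uniq, counts = np.unique(combos, axis=0, return_counts=True)
        for (i5, i3, it, ed, sn), c in zip(uniq, counts):
            shift5, shift3, tail = s5_vals[i5], s3_vals[i3], tail_opts[it]
            insert = list(locus.hairpin_seq[moff + shift5 : moff + mlen + shift3])
            applied_edit = False
            if ed and lt.edit_site is not None:
                pos = lt.edit_site - shift5
                if 0 <= pos < len(insert):
                    insert[pos] = "G"
                    applied_edit = True
            applied_snp = False
            if sn and lt.snp_site_info is not None:
                off, alt = lt.snp_site_info
                pos = off - shift5
                if 0 <= pos < len(insert):
                    insert[pos] = alt
                    applied_snp = True
            insert = "".join(insert) + tail
            L = len(insert)
            p_err = 1 - (1 - profile.plate_error_rate) ** L
            n_err = rng.binomial(c, p_err) if profile.plate_error_rate > 0 else 0
            n_lowq = rng.binomial(c, profile.low_q_read_frac) if profile.low_q_read_frac > 0 else 0
            lowq_idx = set(rng.choice(c, size=n_lowq, replace=False)) if n_lowq else set()
            base_seq = insert + adapter
            base_qual = chr(Q_HI + 33) * len(base_seq)
            for j in range(int(c)):
                seq, qual = base_seq, base_qual
                if j < n_err:
                    pos = int(rng.integers(L))
                    alt = _other_base(rng, insert[pos])
                    seq = base_seq[:pos] + alt + base_seq[pos + 1 :]
                if j in lowq_idx:
                    qpos = int(rng.integers(L))
                    qual = base_qual[:qpos] + chr(Q_LOW + 33) + base_qual[qpos + 1 :]
                records.append(ReadRecord(f"{sample_id}.{read_i}", seq, qual))
                read_i += 1
            truth_rows.append({
                "sample_id": sample_id, "locus": name, "shift5": shift5,
                "shift3": shift3, "tail": tail, "edited": bool(applied_edit),
                "snp": bool(applied_snp), "count": int(c), "n_err": int(n_err),
                "n_lowq": int(n_lowq),
            })
    truth = pd.DataFrame(truth_rows)
    return records, truth


def _other_base(rng, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


# ---------------------------------------------------------------------------
# cohort simulation


ENZYMES = ["ADAR", "ADARB1", "TENT2", "TENT4B", "TENT3A", "TENT3B"]


class CohortData:
    """Three simulated cohorts with lazily generated reads.

    Per-sample FASTQ records are regenerated deterministically on demand
    from the master seed, so the full benchmark never has to be held in
    memory.  ``truth_freq`` records every realized per-sample event
    frequency; ``enzymes`` holds the simulated gene-level modifier-enzyme
    expression matrix and ``probes``/``probe_map`` a probe-level version
    of it for the probe-collapsing step.
    """

    def __init__(self, config, bundle, sheet, profiles, truth_freq,
                 enzymes, probes, probe_map, seed):
        self.config = config
        self.bundle = bundle
        self.sheet = sheet
        self.profiles = profiles
        self.truth_freq = truth_freq
        self.enzymes = enzymes
        self.probes = probes
        self.probe_map = probe_map
        self.seed = seed
        self._order = {sid: i for i, sid in enumerate(sheet["sample_id"])}

    def sample_ids(self) -> list[str]:
        return list(self.sheet["sample_id"])

    def adapter_for(self, sample_id: str) -> str:
        cohort = self.sheet.set_index("sample_id").loc[sample_id, "cohort"]
        for cc in self.config.cohorts:
            if cc.name == cohort:
                return cc.adapter
        raise KeyError(cohort)

    def reads(self, sample_id: str) -> tuple[list[ReadRecord], pd.DataFrame]:
        child = np.random.SeedSequence(entropy=self.seed, spawn_key=(self._order[sample_id],))
        sample_seed = int(child.generate_state(1)[0] % (2**31))
        return simulate_sample(
            self.bundle, self.profiles[sample_id], self.config.n_reads,
            self.adapter_for(sample_id), sample_seed, sample_id=sample_id,
            config=self.config,
        )

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.bundle.write_dir(outdir / "reference")
        self.sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
        self.truth_freq.to_csv(outdir / "truth_frequencies.tsv", sep="\t", index=False)
        self.enzymes.to_csv(outdir / "enzyme_expression.tsv", sep="\t")
        self.probes.to_csv(outdir / "enzyme_probes.tsv", sep="\t")
        self.probe_map.to_csv(outdir / "probe_map.tsv", sep="\t", index=False)
        from .read_prep import write_fastq

        for cohort in self.sheet["cohort"].unique():
            (outdir / cohort).mkdir(exist_ok=True)
        for sid in self.sample_ids():
            cohort = self.sheet.set_index("sample_id").loc[sid, "cohort"]
            records, truth = self.reads(sid)
            write_fastq(records, outdir / cohort / f"{sid}.fastq")
            truth.to_csv(outdir / cohort / f"{sid}.truth.tsv", sep="\t", index=False)


def simulate_cohorts(config: SimulationConfig, seed: int) -> CohortData:
    """Simulate the full paired three-cohort benchmark design."""
    config.validate()
    bundle = make_reference(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(10_001,)))

    rows = []
    profiles: dict[str, TruthProfile] = {}
    truth_rows = []
    enzyme_cols = {}
    for cc in config.cohorts:
        plates = cc.plates
        for i in range(cc.n_pairs):
            patient = f"{cc.name}-P{i:03d}"
            plate_name, plate_rate = plates[i % len(plates)]
            u_pat = rng.normal(size=2)  # latent ADAR / ADARB1 factors
            stage = _draw_stage(rng, config.stage_iii_frac)
            os_time, os_event = _draw_survival(rng, config, u_pat)
            for group in ("ANL", "LUAD"):
                sid = f"{cc.name}-{group}-{i:03d}"
                u_smp = 0.8 * u_pat + 0.6 * rng.normal(size=2)
                profile = _build_profile(config, rng, group, u_smp, plate_rate)
                profiles[sid] = profile
                rows.append({
                    "sample_id": sid, "cohort": cc.name, "group": group,
                    "patient_id": patient, "plate": f"{cc.name}:{plate_name}",
                    "adapter": cc.adapter,
                    "stage": stage if group == "LUAD" else "",
                    "os_time": os_time if group == "LUAD" else np.nan,
                    "os_event": os_event if group == "LUAD" else np.nan,
                })
                enzyme_cols[sid] = _draw_enzymes(rng, group, u_smp)
                for name, lt in profile.loci.items():
                    if lt.edit_freq:
                        truth_rows.append((sid, cc.name, group, name, "edit",
                                           str(lt.edit_site), lt.edit_freq))
                    for base, f in lt.nta_freqs.items():
                        truth_rows.append((sid, cc.name, group, name, "nta", base, f))
                    for s, f in lt.shift5_freqs.items():
                        truth_rows.append((sid, cc.name, group, name, "shift5", str(s), f))

    sheet = pd.DataFrame(rows)
    truth_freq = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "cohort", "group", "locus", "event_type", "event", "true_frequency"],
    )
    enzymes = pd.DataFrame(enzyme_cols, index=ENZYMES)
    probes, probe_map = _probe_tables(rng, enzymes)
    return CohortData(config, bundle, sheet, profiles, truth_freq, enzymes,
                      probes, probe_map, seed)


def _build_profile(config, rng, group, u_smp, plate_rate) -> TruthProfile:
    is_luad = group == "LUAD"
    loci = {}
    for lc in config.loci:
        lt = LocusTruth(edit_site=lc.edit_site, snp_site_info=lc.snp_site)
        noise = math.exp(config.sigma_sample * rng.normal())
        if lc.edit_site is not None and lc.edit_freq > 0:
            f = lc.edit_freq + (lc.edit_group_effect if is_luad else 0.0)
            if lc.edit_coupling == "ADAR":
                f *= math.exp(config.enzyme_coupling * u_smp[0])
            elif lc.edit_coupling == "ADARB1":
                f *= math.exp(config.enzyme_coupling * u_smp[1])
            lt.edit_freq = float(np.clip(f * noise, 0.0, 0.9))
        for base, f0 in lc.nta_freqs.items():
            f = f0 + (lc.nta_group_effects.get(base, 0.0) if is_luad else 0.0)
            f *= math.exp(config.sigma_sample * rng.normal())
            lt.nta_freqs[base] = float(np.clip(f, 0.0, 0.5))
        for s, f0 in lc.shift5_freqs.items():
            f = f0 + (lc.shift5_group_effects.get(s, 0.0) if is_luad else 0.0)
            f *= math.exp(config.sigma_sample * rng.normal())
            lt.shift5_freqs[s] = float(np.clip(f, 0.0, 0.5))
        if lc.snp_site is not None:
            lt.snp_freq = lc.snp_freq
        loci[lc.name] = lt
    abundance = {lc.name: lc.abundance * math.exp(config.sigma_patient * rng.normal())
                 for lc in config.loci}
    return TruthProfile(
        abundance=abundance, loci=loci, plate_error_rate=plate_rate,
        low_q_read_frac=config.low_q_read_frac,
        shift3_freqs=dict(config.shift3_freqs),
        tail_len2_frac=config.tail_len2_frac,
    )


def _draw_stage(rng, frac_iii: float) -> str:
    if rng.random() < frac_iii:
        return "IIIA"
    return str(rng.choice(["IA", "IB", "IIA", "IIB"]))


def _draw_survival(rng, config, u_pat) -> tuple[float, int]:
    """Overall survival coupled to the patient's editing latent: lower
    editing (lower latent) means a higher hazard."""
    u_edit = (u_pat[0] + u_pat[1]) / math.sqrt(2)
    lam = math.log(2) / config.survival_median_months * math.exp(-config.survival_beta * u_edit)
    t = rng.exponential(1 / lam)
    censor = rng.uniform(6, 72)
    return (round(min(t, censor), 2), int(t <= censor))


def _draw_enzymes(rng, group, u_smp) -> dict:
    is_luad = group == "LUAD"
    vals = {
        "ADAR": 5.0 + 0.5 * u_smp[0] + (0.35 if is_luad else 0.0),
        "ADARB1": 5.0 + 0.5 * u_smp[1] - (0.40 if is_luad else 0.0),
        "TENT2": 4.0, "TENT4B": 4.0,
        "TENT3A": 4.0 + (0.3 if is_luad else 0.0),
        "TENT3B": 4.0 + (0.3 if is_luad else 0.0),
    }
    return {g: math.exp(v + 0.15 * rng.normal()) for g, v in vals.items()}


def _probe_tables(rng, enzymes: pd.DataFrame):
    """Probe-level expression: 1-3 probes per gene, each a scaled, noisy
    copy of the gene signal; the highest-mean probe is the informative one."""
    probe_rows = {}
    map_rows = []
    for gi, gene in enumerate(enzymes.index):
        n_probes = 1 + gi % 3
        for p in range(n_probes):
            pid = f"ILMN_{gi:02d}{p:02d}"
            scale = 1.0 if p == 0 else 0.3 / (p + 1)
            noise = np.exp(0.05 * rng.normal(size=enzymes.shape[1]))
            probe_rows[pid] = enzymes.loc[gene].to_numpy() * scale * noise
            map_rows.append({"probe": pid, "gene": gene})
    probes = pd.DataFrame(probe_rows, index=enzymes.columns).T
    return probes, pd.DataFrame(map_rows)
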