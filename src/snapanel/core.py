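"""Domain types and the dye/strand algebra shared by all snapanel modules.

The central objects model one multiplex SNaPshot minisequencing assay: a set
of biallelic SNV targets, the flanking multiplex-PCR primer pairs that
amplify them, and one single-base-extension (minisequencing) primer per
target whose 3' end abuts the interrogated position.  Genotype output is
always reported on the genome plus strand as given by each target's ref/alt
alleles; primer-strand bases are internal bookkeeping.

Coordinates are 1-based and intervals inclusive throughout (HGVS/VCF
compatible); conversion to half-open happens only inside sequence slicing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional

from .errors import AlphabetError, CoverageError, ValidationError

Strand = Literal["plus", "minus"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
NUCLEOTIDES = frozenset("ACGT")
NUCLEOTIDES_N = frozenset("ACGTN")

#: Default mapping of incorporated ddNTP base to fluorescence channel
#: (ABI SNaPshot chemistry): A green, C black, G blue, T red.
DEFAULT_DYE_MAP = {"A": "green", "C": "black", "G": "blue", "T": "red"}

#: Common 40-mer neutral tail whose suffixes pad the extension primers.
MASTER_TAIL = "aactgactaaactaggtgccacgtcgtgaaagtctgacaa"


def _check_alphabet(seq: str, allow_n: bool = True) -> str:
    allowed = NUCLEOTIDES_N if allow_n else NUCLEOTIDES
    up = seq.upper()
    bad = set(up) - allowed
    if bad:
        raise AlphabetError(
            f"non-nucleotide character(s) {sorted(bad)} in sequence {seq[:30]!r}"
        )
    return up


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (case-insensitive, N allowed)."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    _check_alphabet(base)
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class SnpTarget:
    """One biallelic SNV with plus-strand alleles and a 1-based coordinate."""

    rsid: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    locus_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in NUCLEOTIDES:
                raise ValidationError(
                    f"{self.rsid}: allele {allele!r} not a single ACGT base"
                )
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"{self.rsid}: ref and alt alleles are identical")
        if self.pos < 1:
            raise ValidationError(f"{self.rsid}: position must be >= 1")


@dataclass(frozen=True)
class VariantFeature:
    """A known flanking variant (SNV, insertion or deletion) near a target."""

    id: str
    start: int
    end: int
    kind: Literal["SNV", "insertion", "deletion"]
    alleles: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"{self.id}: start > end")
        if self.kind not in ("SNV", "insertion", "deletion"):
            raise ValidationError(f"{self.id}: unknown variant kind {self.kind!r}")

    def intersects(self, lo: int, hi: int) -> bool:
        """True if [start, end] overlaps the inclusive interval [lo, hi]."""
        return self.start <= hi and self.end >= lo


@dataclass
class ReferenceContext:
    """A plus-strand reference window with optional known flanking variants."""

    chrom: str
    window_start: int
    sequence: str
    known_variants: list[VariantFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = _check_alphabet(self.sequence, allow_n=True)
        if self.window_start < 1:
            raise ValidationError("window_start must be >= 1")

    @property
    def window_end(self) -> int:
        return self.window_start + len(self.sequence) - 1

    def covers(self, lo: int, hi: int) -> bool:
        return self.window_start <= lo and hi <= self.window_end

    def slice(self, lo: int, hi: int) -> str:
        """Plus-strand bases over the 1-based inclusive interval [lo, hi]."""
        if not self.covers(lo, hi):
            raise CoverageError(
                f"interval {lo}-{hi} outside window "
                f"{self.window_start}-{self.window_end} on {self.chrom}"
            )
        off = lo - self.window_start
        return self.sequence[off : off + (hi - lo + 1)]

    def base_at(self, pos: int) -> str:
        return self.slice(pos, pos)


class DyeMap:
    """Bijective mapping of ddNTP base to fluorescence colour."""

    def __init__(self, mapping: Optional[dict[str, str]] = None):
        self.mapping = dict(mapping or DEFAULT_DYE_MAP)
        if set(self.mapping) != NUCLEOTIDES:
            raise ValidationError("dye map must cover exactly {A,C,G,T}")
        if len(set(self.mapping.values())) != 4:
            raise ValidationError("dye map must be bijective over {A,C,G,T}")

    def __getitem__(self, base: str) -> str:
        base = base.upper()
        if base not in self.mapping:
            raise AlphabetError(f"no dye for base {base!r}")
        return self.mapping[base]

    def __eq__(self, other):
        return isinstance(other, DyeMap) and self.mapping == other.mapping

    def colours(self) -> set[str]:
        return set(self.mapping.values())

    def to_dict(self) -> dict[str, str]:
        return dict(self.mapping)


def dye_for_base(base: str, dye_map: Optional[DyeMap] = None) -> str:
    """Fluorescence colour emitted when `base` is the incorporated ddNTP."""
    return (dye_map or DyeMap())[base]


def detected_bases(target: SnpTarget, strand: Strand) -> tuple[str, str]:
    """Bases incorporated on the primer-sense strand for (ref, alt).

    A plus-strand extension primer is extended with the plus-strand allele
    itself; a minus-strand primer is extended with its complement.
    """
    if strand == "plus":
        return target.ref_allele, target.alt_allele
    if strand == "minus":
        return complement(target.ref_allele), complement(target.alt_allele)
    raise ValidationError(f"strand must be 'plus' or 'minus', got {strand!r}")


@dataclass(frozen=True)
class DesignConstraints:
    """Numeric design rules with their assay defaults.

    Defaults reflect the multiplex SNaPshot chemistry on an ABI capillary
    instrument: PCR primers 17-29 nt with Tm 57-64 degC, extension products
    sized against a 15-120 nt standard, a minimum 4 nt length stagger
    between same-dye products (3 nt being the empirical resolution floor),
    and a fixed neutral master tail whose suffixes pad short primers, with
    poly(C) padding beyond its length.
    """

    tm_min: float = 57.0
    tm_max: float = 64.0
    pcr_len_min: int = 17
    pcr_len_max: int = 29
    same_dye_min_gap: int = 4
    empirical_min_gap: int = 3
    readable_window: tuple[int, int] = (15, 120)
    master_tail: str = MASTER_TAIL
    pad_base: str = "C"
    annealing_temp_ext: float = 52.0  # metadata only

    def __post_init__(self):
        if not self.tm_min < self.tm_max:
            raise ValidationError("tm_min must be < tm_max")
        if not self.pcr_len_min < self.pcr_len_max:
            raise ValidationError("pcr_len_min must be < pcr_len_max")
        if self.same_dye_min_gap < self.empirical_min_gap:
            raise ValidationError("same_dye_min_gap must be >= empirical_min_gap")
        _check_alphabet(self.master_tail, allow_n=False)
        _check_alphabet(self.pad_base, allow_n=False)


@dataclass
class PcrPrimerPair:
    """A flanking PCR primer pair and the amplicon it defines.

    Genomic coordinates are optional: panels imported from printed tables
    carry only the amplicon length; sequence/coordinate consistency is
    checked against a ReferenceContext when one is available.
    """

    covered_rsids: list[str]
    fwd_seq: str
    rev_seq: str
    reaction: str
    amplicon_len: int
    conc_fwd: float = 0.0
    conc_rev: float = 0.0
    amplicon_start: Optional[int] = None
    amplicon_end: Optional[int] = None
    seq_primer: Optional[str] = None

    def __post_init__(self):
        self.fwd_seq = _check_alphabet(self.fwd_seq, allow_n=False)
        self.rev_seq = _check_alphabet(self.rev_seq, allow_n=False)
        if self.amplicon_len < len(self.fwd_seq) + 1 or self.amplicon_len < len(
            self.rev_seq
        ) + 1:
            raise ValidationError(
                f"amplicon of {self.amplicon_len} bp cannot contain both primers"
            )
        if self.amplicon_start is not None and self.amplicon_end is not None:
            if self.amplicon_end - self.amplicon_start + 1 != self.amplicon_len:
                raise ValidationError(
                    "amplicon_len inconsistent with amplicon_start/amplicon_end"
                )

    def check_against(self, context: ReferenceContext) -> None:
        """Verify primer/amplicon coordinate invariants on a reference."""
        if self.amplicon_start is None or self.amplicon_end is None:
            raise ValidationError("pair has no coordinates to check")
        s, e = self.amplicon_start, self.amplicon_end
        if context.slice(s, s + len(self.fwd_seq) - 1) != self.fwd_seq:
            raise ValidationError("fwd_seq does not match plus strand at amplicon_start")
        if (
            reverse_complement(context.slice(e - len(self.rev_seq) + 1, e))
            != self.rev_seq
        ):
            raise ValidationError(
                "rev_seq is not the reverse complement of the amplicon 3' end"
            )

    def covers_position(self, pos: int) -> bool:
        """True if pos lies strictly inside the amplicon (coords required)."""
        if self.amplicon_start is None or self.amplicon_end is None:
            raise ValidationError("pair has no coordinates")
        return self.amplicon_start < pos < self.amplicon_end


@dataclass
class ExtensionPrimer:
    """A minisequencing primer: 5' neutral tail + genomic core.

    The core's 3' base is the template-adjacent base immediately 5' of the
    SNP on the primer-sense strand; single-base extension appends the
    allele as read on that strand.  Tails are kept lower-case in serialized
    form, cores upper-case.
    """

    rsid: str
    strand: Strand
    core_seq: str
    tail_seq: str
    detected_base_ref: str
    detected_base_alt: str
    dye_ref: str
    dye_alt: str
    conc: float = 0.0
    direction_label: str = ""  # printed assay F/R label, metadata only

    def __post_init__(self):
        if self.strand not in ("plus", "minus"):
            raise ValidationError(f"{self.rsid}: bad strand {self.strand!r}")
        _check_alphabet(self.core_seq, allow_n=False)
        if self.tail_seq:
            _check_alphabet(self.tail_seq, allow_n=False)
        self.core_seq = self.core_seq.upper()
        self.tail_seq = self.tail_seq.lower()
        for b in (self.detected_base_ref, self.detected_base_alt):
            if b.upper() not in NUCLEOTIDES:
                raise ValidationError(f"{self.rsid}: bad detected base {b!r}")
        if self.dye_ref == self.dye_alt:
            raise ValidationError(f"{self.rsid}: ref and alt dyes must differ")

    @property
    def tail_len(self) -> int:
        return len(self.tail_seq)

    @property
    def total_len(self) -> int:
        return len(self.tail_seq) + len(self.core_seq)

    @property
    def sequence(self) -> str:
        """Full primer 5'->3': lower-case tail then upper-case core."""
        return self.tail_seq + self.core_seq

    @property
    def dye_pair(self) -> frozenset:
        return frozenset((self.dye_ref, self.dye_alt))

    def check_against(self, target: SnpTarget, dye_map: DyeMap) -> None:
        """Verify the detected-base / dye algebra against the target."""
        if target.rsid != self.rsid:
            raise ValidationError("primer/target rsid mismatch")
        exp = detected_bases(target, self.strand)
        got = (self.detected_base_ref, self.detected_base_alt)
        if got != exp:
            raise ValidationError(
                f"{self.rsid}: detected bases {got} != expected {exp} "
                f"for {self.strand} strand"
            )
        if (self.dye_ref, self.dye_alt) != (dye_map[exp[0]], dye_map[exp[1]]):
            raise ValidationError(f"{self.rsid}: dyes inconsistent with dye map")


@dataclass
class PanelDesign:
    """A complete assay: targets, PCR pairs, extension primers, rules."""

    name: str
    targets: list[SnpTarget]
    pcr_pairs: list[PcrPrimerPair]
    ext_primers: list[ExtensionPrimer]
    constraints: DesignConstraints = field(default_factory=DesignConstraints)
    dye_map: DyeMap = field(default_factory=DyeMap)
    mobility: Optional["object"] = None  # readout.MobilityModel, set lazily

    def __post_init__(self):
        target_ids = [t.rsid for t in self.targets]
        if len(set(target_ids)) != len(target_ids):
            raise ValidationError("duplicate target rsids in panel")
        primer_ids = [p.rsid for p in self.ext_primers]
        if sorted(primer_ids) != sorted(target_ids):
            raise ValidationError(
                "panel must have exactly one extension primer per target"
            )
        coverage: dict[str, int] = {t: 0 for t in target_ids}
        for pair in self.pcr_pairs:
            for rsid in pair.covered_rsids:
                if rsid in coverage:
                    coverage[rsid] += 1
        uncovered = [t for t, n in coverage.items() if n != 1]
        if uncovered:
            raise ValidationError(
                f"targets not covered by exactly one PCR pair: {uncovered}"
            )

    def target(self, rsid: str) -> SnpTarget:
        for t in self.targets:
            if t.rsid == rsid:
                return t
        raise KeyError(rsid)

    def primer(self, rsid: str) -> ExtensionPrimer:
        for p in self.ext_primers:
            if p.rsid == rsid:
                return p
        raise KeyError(rsid)

    def validate_primer_algebra(self) -> None:
        for p in self.ext_primers:
            p.check_against(self.target(p.rsid), self.dye_map)


__all__ = [
    "DEFAULT_DYE_MAP",
    "MASTER_TAIL",
    "DesignConstraints",
    "DyeMap",
    "ExtensionPrimer",
    "PanelDesign",
    "PcrPrimerPair",
    "ReferenceContext",
    "SnpTarget",
    "Strand",
    "VariantFeature",
    "complement",
    "detected_bases",
    "dye_for_base",
    "reverse_complement",
]
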