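"""Packaged assay fixtures and the toy-genome generator.

Ships the two published panels — the 12-plex BCL11A and 16-plex HBS1L-MYB
multiplex SNaPshot assays — as validated tables: 28 SNV targets, 22
multiplex-PCR primer pairs (9 + 13) and 28 extension primers.  Because no
reference genome is packaged, the toy-genome generator synthesises each
amplicon as the real printed primers around seeded random filler, embedded
in random background, so every in-silico operation (PCR, uniqueness scan,
extension design, simulation) runs end to end with zero network access.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core import (
    DesignConstraints,
    DyeMap,
    ExtensionPrimer,
    PanelDesign,
    PcrPrimerPair,
    ReferenceContext,
    SnpTarget,
)
from .errors import ConstructionError, FixtureError

LOCI = ("BCL11A", "HBS1L-MYB")

_CHECKSUMS = {
    "targets.tsv": "ed8db453d019959405918bd646aeb6cc89920e725d663e89e95294f43c317488",
    "pcr_primers.tsv": "29f5fe9b422f7435e4daf62dea7fc97b1cbbe465c825752da770398c447566b6",
    "ext_primers.tsv": "99506582eabb9bf1e56bd4853979a9ad237532ae881f6264a8bb30b33997f252",
}

_EXPECTED_COUNTS = {"BCL11A": (12, 9, 12), "HBS1L-MYB": (16, 13, 16)}


def _read_packaged(name: str) -> pd.DataFrame:
    ref = resources.files("snapanel.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureError(f"packaged fixture {name} is corrupted (checksum mismatch)")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t", dtype=str)


def split_tail_core(primer_seq: str) -> tuple[str, str]:
    """Split a serialized extension primer into (lower-case tail, core)."""
    i = 0
    while i < len(primer_seq) and primer_seq[i].islower():
        i += 1
    tail, core = primer_seq[:i], primer_seq[i:]
    if not core or not core.isupper():
        raise FixtureError(f"malformed primer sequence {primer_seq!r}")
    return tail, core


@dataclass
class FixtureSet:
    """The published panel tables, parsed and invariant-checked."""

    targets_table: pd.DataFrame
    pcr_table: pd.DataFrame
    ext_table: pd.DataFrame
    dye_map: DyeMap = field(default_factory=DyeMap)
    constraints: DesignConstraints = field(default_factory=DesignConstraints)

    def targets(self, locus: str) -> list[SnpTarget]:
        rows = self.targets_table[self.targets_table["locus"] == locus]
        return [
            SnpTarget(
                rsid=r.rsid,
                chrom=r.chrom,
                pos=int(r.pos),
                ref_allele=r.ref,
                alt_allele=r.alt,
                locus_label=r.locus,
            )
            for r in rows.itertuples()
        ]

    def pcr_pairs(self, locus: str) -> list[PcrPrimerPair]:
        rows = self.pcr_table[self.pcr_table["locus"] == locus]
        out = []
        for r in rows.itertuples():
            out.append(
                PcrPrimerPair(
                    covered_rsids=r.covered_rsids.split(","),
                    fwd_seq=r.fwd_seq,
                    rev_seq=r.rev_seq,
                    reaction=r.reaction,
                    amplicon_len=int(r.amplicon_len),
                    conc_fwd=float(r.conc_uM),
                    conc_rev=float(r.conc_uM),
                    seq_primer=None if pd.isna(r.seq_primer) else r.seq_primer,
                )
            )
        return out

    def ext_primers(self, locus: str) -> list[ExtensionPrimer]:
        targets = {t.rsid: t for t in self.targets(locus)}
        rows = self.ext_table[self.ext_table["locus"] == locus]
        out = []
        for r in rows.itertuples():
            tail, core = split_tail_core(r.primer_seq)
            target = targets[r.rsid]
            from .core import detected_bases

            ref_b, alt_b = detected_bases(target, r.strand)
            primer = ExtensionPrimer(
                rsid=r.rsid,
                strand=r.strand,
                core_seq=core,
                tail_seq=tail,
                detected_base_ref=ref_b,
                detected_base_alt=alt_b,
                dye_ref=self.dye_map[ref_b],
                dye_alt=self.dye_map[alt_b],
                conc=float(r.conc_uM),
                direction_label=r.direction,
            )
            if primer.total_len != int(r.size_bp):
                raise FixtureError(
                    f"{r.rsid}: sequence length {primer.total_len} != printed "
                    f"size {r.size_bp}"
                )
            out.append(primer)
        return out

    def panel(self, locus: str) -> PanelDesign:
        if locus not in LOCI:
            raise KeyError(f"unknown locus {locus!r}; expected one of {LOCI}")
        panel = PanelDesign(
            name=locus,
            targets=self.targets(locus),
            pcr_pairs=self.pcr_pairs(locus),
            ext_primers=self.ext_primers(locus),
            constraints=self.constraints,
            dye_map=self.dye_map,
        )
        panel.validate_primer_algebra()
        return panel


def load_fixtures() -> FixtureSet:
    """Load and validate the packaged panel tables."""
    fs = FixtureSet(
        targets_table=_read_packaged("targets.tsv"),
        pcr_table=_read_packaged("pcr_primers.tsv"),
        ext_table=_read_packaged("ext_primers.tsv"),
    )
    for locus, (n_targets, n_pcr, n_ext) in _EXPECTED_COUNTS.items():
        if len(fs.targets(locus)) != n_targets:
            raise FixtureError(f"{locus}: expected {n_targets} targets")
        if len(fs.pcr_table[fs.pcr_table["locus"] == locus]) != n_pcr:
            raise FixtureError(f"{locus}: expected {n_pcr} PCR rows")
        if len(fs.ext_table[fs.ext_table["locus"] == locus]) != n_ext:
            raise FixtureError(f"{locus}: expected {n_ext} extension rows")
        fs.panel(locus)  # full invariant check
    return fs


@dataclass
class ToyGenome:
    """Synthetic reference embedding each fixture amplicon exactly once."""

    seed: int
    sequences: dict[str, str]
    amplicon_coords: dict[str, tuple[int, int]]  # first covered rsid -> interval
    targets: list[SnpTarget]
    locus_chrom: dict[str, str]

    def context(self, chrom: str) -> ReferenceContext:
        return ReferenceContext(
            chrom=chrom, window_start=1, sequence=self.sequences[chrom]
        )

    def contexts(self) -> dict[str, ReferenceContext]:
        return {c: self.context(c) for c in self.sequences}


def build_toy_genome(fixtures: FixtureSet, seed: int = 0) -> ToyGenome:
    """Synthesise a toy genome from the packaged PCR table.

    Each pseudo-amplicon is ``fwd + seeded random filler + revcomp(rev)``
    with the printed total length, separated by 150-300 bp of random
    background; toy SNV targets are planted in the filler of their
    amplicon (ref = the planted base, alt drawn from the remaining three).
    Byte-identical output for identical seeds.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def rand_seq(n: int) -> str:
        return "".join(bases[rng.integers(0, 4, size=n)])

    sequences: dict[str, str] = {}
    coords: dict[str, tuple[int, int]] = {}
    toy_targets: list[SnpTarget] = []
    locus_chrom = {}
    from .core import reverse_complement

    for locus in LOCI:
        chrom = "toy_" + locus.replace("-", "_")
        locus_chrom[locus] = chrom
        parts: list[str] = []
        cursor = 0
        snp_plan: list[tuple[str, int]] = []  # (rsid, 1-based chrom position)
        for pair in fixtures.pcr_pairs(locus):
            gap = int(rng.integers(150, 301))
            parts.append(rand_seq(gap))
            cursor += gap
            filler_len = pair.amplicon_len - len(pair.fwd_seq) - len(pair.rev_seq)
            if filler_len < 0:
                raise ConstructionError(
                    f"{pair.covered_rsids}: printed amplicon of "
                    f"{pair.amplicon_len} bp shorter than its primers"
                )
            amplicon = pair.fwd_seq + rand_seq(filler_len) + reverse_complement(
                pair.rev_seq
            )
            start = cursor + 1
            end = cursor + pair.amplicon_len
            coords[pair.covered_rsids[0]] = (start, end)
            # plant covered SNPs evenly inside the filler
            k = len(pair.covered_rsids)
            flo = start + len(pair.fwd_seq)  # first filler position
            fhi = end - len(pair.rev_seq)  # last filler position
            for i, rsid in enumerate(pair.covered_rsids):
                pos = flo + (i + 1) * (fhi - flo) // (k + 1)
                snp_plan.append((rsid, pos))
            parts.append(amplicon)
            cursor = end
        parts.append(rand_seq(int(rng.integers(150, 301))))
        seq = "".join(parts)
        for rsid, pos in snp_plan:
            ref = seq[pos - 1]
            others = [b for b in "ACGT" if b != ref]
            alt = others[int(rng.integers(0, 3))]
            toy_targets.append(
                SnpTarget(
                    rsid=rsid,
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    locus_label=locus,
                )
            )
        sequences[chrom] = seq
    return ToyGenome(
        seed=seed,
        sequences=sequences,
        amplicon_coords=coords,
        targets=toy_targets,
        locus_chrom=locus_chrom,
    )


__all__ = [
    "FixtureSet",
    "LOCI",
    "ToyGenome",
    "build_toy_genome",
    "load_fixtures",
    "split_tail_core",
]
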