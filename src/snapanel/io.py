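"""Readers and writers for the external formats.

Targets come in as TSV or VCF, references as FASTA, panels round-trip
through JSON (with TSV mirrors of the printed table layout), peak tables
as GeneMapper-style CSV exports, and genotype calls go out as VCF v4.2
plus a TSV mirror.  Parsing is strict: malformed rows raise with the
offending line named.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    DesignConstraints,
    DyeMap,
    ExtensionPrimer,
    PanelDesign,
    PcrPrimerPair,
    ReferenceContext,
    SnpTarget,
)
from .errors import ParseError
from .readout import PEAK_COLUMNS, CallResult, MobilityModel

# ---------------------------------------------------------------- targets


def read_targets_tsv(path) -> list[SnpTarget]:
    """Targets TSV: rsid, chrom, pos, ref, alt[, locus]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"rsid", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for i, r in enumerate(df.itertuples(), start=2):
        try:
            out.append(
                SnpTarget(
                    rsid=r.rsid,
                    chrom=r.chrom,
                    pos=int(r.pos),
                    ref_allele=r.ref,
                    alt_allele=r.alt,
                    locus_label=getattr(r, "locus", "") or "",
                )
            )
        except Exception as exc:
            raise ParseError(f"{path} line {i}: {exc}") from exc
    return out


def read_targets_vcf(path) -> list[SnpTarget]:
    """Biallelic SNV targets from a VCF (ID, CHROM, POS, REF, single ALT)."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ParseError(
                    f"{path}: {rec.id or rec.pos}: exactly one ALT allele required"
                )
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                raise ParseError(
                    f"{path}: {rec.id or rec.pos}: only SNVs are supported"
                )
            out.append(
                SnpTarget(
                    rsid=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                )
            )
    return out


def read_targets(path) -> list[SnpTarget]:
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return read_targets_vcf(path)
    return read_targets_tsv(path)


def read_known_variants(path) -> dict[str, list]:
    """Known flanking variants (SNVs and indels), grouped by chromosome.

    VCF: the REF/ALT length difference classifies SNV vs insertion vs
    deletion; a deletion's footprint spans its deleted reference bases.
    TSV needs columns id, chrom, start, end, kind.
    """
    from .core import VariantFeature

    out: dict[str, list] = {}
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        import pysam

        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                alt = rec.alts[0] if rec.alts else rec.ref
                if len(rec.ref) == len(alt) == 1:
                    kind, start, end = "SNV", rec.pos, rec.pos
                elif len(rec.ref) > len(alt):
                    # deleted bases follow the anchor base
                    kind, start, end = "deletion", rec.pos + 1, rec.pos + len(rec.ref) - 1
                else:
                    kind, start, end = "insertion", rec.pos, rec.pos + 1
                out.setdefault(rec.chrom, []).append(
                    VariantFeature(
                        id=rec.id or f"{rec.chrom}:{rec.pos}",
                        start=start,
                        end=end,
                        kind=kind,
                        alleles=f"{rec.ref}>{alt}",
                    )
                )
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"id", "chrom", "start", "end", "kind"} - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
        for i, r in enumerate(df.itertuples(), start=2):
            try:
                out.setdefault(r.chrom, []).append(
                    VariantFeature(
                        id=r.id, start=int(r.start), end=int(r.end), kind=r.kind
                    )
                )
            except Exception as exc:
                raise ParseError(f"{path} line {i}: {exc}") from exc
    return out


# ---------------------------------------------------------------- reference


def read_reference(path, window_starts: Optional[dict[str, int]] = None) -> dict:
    """FASTA -> {name: ReferenceContext}; window starts default to 1 and
    may be overridden per contig (for windows cut out of a larger genome)."""
    window_starts = window_starts or {}
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = ReferenceContext(
            chrom=rec.id,
            window_start=int(window_starts.get(rec.id, 1)),
            sequence=str(rec.seq),
        )
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- panel JSON


def panel_to_dict(panel: PanelDesign) -> dict:
    cons = panel.constraints
    return {
        "name": panel.name,
        "constraints": {
            "tm_min": cons.tm_min,
            "tm_max": cons.tm_max,
            "pcr_len_min": cons.pcr_len_min,
            "pcr_len_max": cons.pcr_len_max,
            "same_dye_min_gap": cons.same_dye_min_gap,
            "empirical_min_gap": cons.empirical_min_gap,
            "readable_window": list(cons.readable_window),
            "master_tail": cons.master_tail,
            "pad_base": cons.pad_base,
            "annealing_temp_ext": cons.annealing_temp_ext,
        },
        "dye_map": panel.dye_map.to_dict(),
        "mobility": dict(panel.mobility.params) if panel.mobility else {},
        "targets": [
            {
                "rsid": t.rsid,
                "chrom": t.chrom,
                "pos": t.pos,
                "ref": t.ref_allele,
                "alt": t.alt_allele,
                "locus": t.locus_label,
            }
            for t in panel.targets
        ],
        "pcr_pairs": [
            {
                "covered_rsids": p.covered_rsids,
                "fwd_seq": p.fwd_seq,
                "rev_seq": p.rev_seq,
                "reaction": p.reaction,
                "amplicon_len": p.amplicon_len,
                "conc_fwd": p.conc_fwd,
                "conc_rev": p.conc_rev,
                "amplicon_start": p.amplicon_start,
                "amplicon_end": p.amplicon_end,
                "seq_primer": p.seq_primer,
            }
            for p in panel.pcr_pairs
        ],
        "ext_primers": [
            {
                "rsid": e.rsid,
                "strand": e.strand,
                "sequence": e.sequence,  # lower-case tail + upper-case core
                "detected_base_ref": e.detected_base_ref,
                "detected_base_alt": e.detected_base_alt,
                "dye_ref": e.dye_ref,
                "dye_alt": e.dye_alt,
                "conc": e.conc,
                "direction_label": e.direction_label,
            }
            for e in panel.ext_primers
        ],
    }


def panel_from_dict(d: dict) -> PanelDesign:
    from .fixtures import split_tail_core

    try:
        cons_d = d["constraints"]
        constraints = DesignConstraints(
            tm_min=cons_d["tm_min"],
            tm_max=cons_d["tm_max"],
            pcr_len_min=cons_d["pcr_len_min"],
            pcr_len_max=cons_d["pcr_len_max"],
            same_dye_min_gap=cons_d["same_dye_min_gap"],
            empirical_min_gap=cons_d["empirical_min_gap"],
            readable_window=tuple(cons_d["readable_window"]),
            master_tail=cons_d["master_tail"],
            pad_base=cons_d["pad_base"],
            annealing_temp_ext=cons_d["annealing_temp_ext"],
        )
        targets = [
            SnpTarget(
                rsid=t["rsid"],
                chrom=t["chrom"],
                pos=t["pos"],
                ref_allele=t["ref"],
                alt_allele=t["alt"],
                locus_label=t.get("locus", ""),
            )
            for t in d["targets"]
        ]
        pcr_pairs = [
            PcrPrimerPair(
                covered_rsids=p["covered_rsids"],
                fwd_seq=p["fwd_seq"],
                rev_seq=p["rev_seq"],
                reaction=p["reaction"],
                amplicon_len=p["amplicon_len"],
                conc_fwd=p.get("conc_fwd", 0.0),
                conc_rev=p.get("conc_rev", 0.0),
                amplicon_start=p.get("amplicon_start"),
                amplicon_end=p.get("amplicon_end"),
                seq_primer=p.get("seq_primer"),
            )
            for p in d["pcr_pairs"]
        ]
        ext_primers = []
        for e in d["ext_primers"]:
            tail, core = split_tail_core(e["sequence"])
            ext_primers.append(
                ExtensionPrimer(
                    rsid=e["rsid"],
                    strand=e["strand"],
                    core_seq=core,
                    tail_seq=tail,
                    detected_base_ref=e["detected_base_ref"],
                    detected_base_alt=e["detected_base_alt"],
                    dye_ref=e["dye_ref"],
                    dye_alt=e["dye_alt"],
                    conc=e.get("conc", 0.0),
                    direction_label=e.get("direction_label", ""),
                )
            )
        mobility = MobilityModel(
            {k: tuple(v) for k, v in d.get("mobility", {}).items()}
        )
        panel = PanelDesign(
            name=d["name"],
            targets=targets,
            pcr_pairs=pcr_pairs,
            ext_primers=ext_primers,
            constraints=constraints,
            dye_map=DyeMap(d["dye_map"]),
            mobility=mobility if d.get("mobility") else None,
        )
    except KeyError as exc:
        raise ParseError(f"panel JSON missing field {exc}") from exc
    panel.validate_primer_algebra()
    return panel


def write_panel(panel: PanelDesign, path) -> None:
    Path(path).write_text(json.dumps(panel_to_dict(panel), indent=2) + "\n")


def read_panel(path) -> PanelDesign:
    return panel_from_dict(json.loads(Path(path).read_text()))


def write_panel_tsv(panel: PanelDesign, pcr_path, ext_path) -> None:
    """TSV mirrors of the printed table layout (PCR pairs; ext primers)."""
    pcr_rows = [
        {
            "covered_rsids": ",".join(p.covered_rsids),
            "fwd_seq": p.fwd_seq,
            "rev_seq": p.rev_seq,
            "reaction": p.reaction,
            "amplicon_len": p.amplicon_len,
            "conc_uM": p.conc_fwd,
        }
        for p in panel.pcr_pairs
    ]
    pd.DataFrame(pcr_rows).to_csv(pcr_path, sep="\t", index=False)
    ext_rows = [
        {
            "rsid": e.rsid,
            "strand": e.strand,
            "primer_seq": e.sequence,
            "size_bp": e.total_len,
            "conc_uM": e.conc,
            "detected_alleles": f"{e.detected_base_ref}/{e.detected_base_alt}",
        }
        for e in panel.ext_primers
    ]
    pd.DataFrame(ext_rows).to_csv(ext_path, sep="\t", index=False)


# ---------------------------------------------------------------- peaks


def read_peaks(path) -> pd.DataFrame:
    """Peak CSV with columns sample, dye, size_nt, height."""
    df = pd.read_csv(path)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    extra = set(df.columns) - set(PEAK_COLUMNS)
    if extra:
        import warnings

        warnings.warn(f"{path}: ignoring unknown column(s) {sorted(extra)}")
    for i, r in enumerate(df.itertuples(), start=2):
        if not float(r.size_nt) > 0:
            raise ParseError(f"{path} line {i}: observed size must be > 0")
        if float(r.height) < 0:
            raise ParseError(f"{path} line {i}: height must be >= 0")
    return df[PEAK_COLUMNS]


def write_peaks(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, index=False)


# ---------------------------------------------------------------- calls

_GT = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "no_call": "./."}


def write_calls_vcf(
    result: CallResult, panel: PanelDesign, path, sample: str = "sample1"
) -> None:
    """Genotype calls as a minimal spec-valid VCF v4.2 (plus-strand alleles)."""
    targets = {t.rsid: t for t in panel.targets}
    contig_max: dict[str, int] = {}
    for t in panel.targets:
        contig_max[t.chrom] = max(contig_max.get(t.chrom, 0), t.pos)
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=snapanel",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FILTER=<ID=PASS,Description="All filters passed">',
    ]
    for chrom in sorted(contig_max):
        lines.append(f"##contig=<ID={chrom},length={contig_max[chrom] + 1000}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    ordered = sorted(result.calls, key=lambda c: (targets[c.rsid].chrom, targets[c.rsid].pos))
    for call in ordered:
        t = targets[call.rsid]
        lines.append(
            f"{t.chrom}\t{t.pos}\t{t.rsid}\t{t.ref_allele}\t{t.alt_allele}\t."
            f"\tPASS\t.\tGT\t{_GT[call.status]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_calls_tsv(result: CallResult, panel: PanelDesign, path) -> None:
    targets = {t.rsid: t for t in panel.targets}
    rows = []
    for call in result.calls:
        t = targets[call.rsid]
        rows.append(
            {
                "rsid": call.rsid,
                "chrom": t.chrom,
                "pos": t.pos,
                "genotype": "/".join(call.genotype) if call.genotype else "./.",
                "status": call.status,
                "supporting_peaks": ",".join(map(str, call.supporting_peaks)),
                "flags": ";".join(call.flags),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


__all__ = [
    "panel_from_dict",
    "panel_to_dict",
    "read_known_variants",
    "read_panel",
    "read_peaks",
    "read_reference",
    "read_targets",
    "read_targets_tsv",
    "read_targets_vcf",
    "write_calls_tsv",
    "write_calls_vcf",
    "write_fasta",
    "write_panel",
    "write_panel_tsv",
    "write_peaks",
]
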