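"""Independent panel-constraint checking and PCR-RFLP digest prediction.

The panel checker re-derives every design rule from first principles so it
can audit both freshly designed panels (strict) and panels imported from
printed tables (report-only on dye-spacing, since a tuned assay may rely on
sequence-dependent mobility to separate nominally coincident products).
The RFLP predictor implements the orthogonal wet-lab check in silico:
whether a SNP allele creates or destroys a recognition site, changing the
fragment profile of its amplicon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .core import (
    DesignConstraints,
    PanelDesign,
    ReferenceContext,
    SnpTarget,
    reverse_complement,
)
from .errors import ValidationError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Recognition patterns of the restriction enzymes used for orthogonal
#: genotype verification.
ENZYME_PATTERNS = {
    "AvaII": "GGWCC",
    "AatII": "GACGTC",
    "BstXI": "CCANNNNNNTGG",
    "RsaI": "GTAC",
    "MspI": "CCGG",
    "HinfI": "GANTC",
    "Hpy188III": "TCNNGA",
}


def _iupac_regex(pattern: str) -> str:
    out = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValidationError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        bases = IUPAC[ch]
        out.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(out)


def is_palindromic(pattern: str) -> bool:
    """True when the IUPAC pattern equals its own reverse complement."""
    up = pattern.upper()
    _iupac_regex(up)
    return up == up.translate(_IUPAC_COMPLEMENT)[::-1]


def digest_fragments(
    amplicon: str, pattern: str, cut_offset: int = 0, scan_minus: Optional[bool] = None
) -> list[int]:
    """Fragment lengths after cutting at every recognition-site match.

    The cut falls ``cut_offset`` bases 3' of the 5' end of each match
    (default 0: at the match start).  The plus strand is scanned with
    IUPAC expansion; the reverse strand is additionally scanned only for
    non-palindromic patterns (by default), since palindromic sites appear
    identically on both strands.  Fragments are returned sorted and always
    partition the amplicon.
    """
    if len(pattern) < 4:
        raise ValidationError("recognition pattern must be >= 4 nt")
    seq = amplicon.upper()
    rx = re.compile(f"(?=({_iupac_regex(pattern)}))")
    if scan_minus is None:
        scan_minus = not is_palindromic(pattern)
    cuts = set()
    for m in rx.finditer(seq):
        cuts.add(m.start() + cut_offset)
    if scan_minus:
        rc = reverse_complement(seq)
        L = len(seq)
        for m in rx.finditer(rc):
            # map the minus-strand match back to plus coordinates
            cuts.add(L - (m.start() + len(pattern)) + cut_offset)
    cuts = sorted(c for c in cuts if 0 < c < len(seq))
    bounds = [0] + cuts + [len(seq)]
    return sorted(bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1))


@dataclass
class RflpAssay:
    """Per-allele digest profiles of a SNP-containing amplicon."""

    rsid: str
    enzyme: str
    pattern: str
    fragments_ref: list[int]
    fragments_alt: list[int]

    @property
    def informative(self) -> bool:
        return self.fragments_ref != self.fragments_alt


def rflp_differential(
    target: SnpTarget,
    context: ReferenceContext,
    amplicon_start: int,
    amplicon_end: int,
    pattern: str,
    enzyme: str = "",
) -> RflpAssay:
    """Digest both allele versions of an amplicon and compare profiles.

    Informative when the ref- and alt-allele fragment profiles differ,
    i.e. the SNP creates or destroys a recognition site.
    """
    if not amplicon_start < target.pos < amplicon_end:
        raise ValidationError(f"{target.rsid} not strictly inside the amplicon")
    seq = context.slice(amplicon_start, amplicon_end)
    off = target.pos - amplicon_start
    if seq[off] != target.ref_allele:
        raise ValidationError(
            f"{target.rsid}: reference base {seq[off]} at pos {target.pos} "
            f"does not match ref allele {target.ref_allele}"
        )
    ref_seq = seq
    alt_seq = seq[:off] + target.alt_allele + seq[off + 1 :]
    return RflpAssay(
        rsid=target.rsid,
        enzyme=enzyme,
        pattern=pattern.upper(),
        fragments_ref=digest_fragments(ref_seq, pattern),
        fragments_alt=digest_fragments(alt_seq, pattern),
    )


@dataclass
class Finding:
    rule: str
    severity: str  # error | warning
    message: str


@dataclass
class PanelReport:
    """Per-rule verdicts for a panel; the panel passes iff zero errors."""

    mode: str
    findings: list[Finding] = field(default_factory=list)

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def passed(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        lines = [
            f"panel check ({self.mode} mode): "
            f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"
        ]
        for f in self.findings:
            lines.append(f"  [{f.severity}] {f.rule}: {f.message}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "passed": self.passed,
            "findings": [
                {"rule": f.rule, "severity": f.severity, "message": f.message}
                for f in self.findings
            ],
        }


def check_panel(
    panel: PanelDesign,
    mode: str = "design",
    tm_of=None,
) -> PanelReport:
    """Verify all design constraints of a panel.

    design mode: nominal same-dye length gaps below ``same_dye_min_gap``
    are errors.  import mode: such gaps are downgraded to warnings — a
    validated instrument run may resolve nominal coincidences through
    dye/sequence mobility.  Tm-window findings are always warnings (the
    design Tm scale is calculator-dependent).  ``tm_of`` optionally maps a
    primer sequence to a Tm for that check.
    """
    if mode not in ("design", "import"):
        raise ValidationError(f"mode must be 'design' or 'import', got {mode!r}")
    cons = panel.constraints
    findings: list[Finding] = []
    win_lo, win_hi = cons.readable_window

    for pair in panel.pcr_pairs:
        for label, seq in (("fwd", pair.fwd_seq), ("rev", pair.rev_seq)):
            if not cons.pcr_len_min <= len(seq) <= cons.pcr_len_max:
                findings.append(
                    Finding(
                        "pcr_primer_length",
                        "error",
                        f"{','.join(pair.covered_rsids)} {label} primer is "
                        f"{len(seq)} nt, outside "
                        f"[{cons.pcr_len_min}, {cons.pcr_len_max}]",
                    )
                )
            if tm_of is not None:
                tm = tm_of(seq)
                if not cons.tm_min <= tm <= cons.tm_max:
                    findings.append(
                        Finding(
                            "pcr_primer_tm",
                            "warning",
                            f"{','.join(pair.covered_rsids)} {label} primer Tm "
                            f"{tm:.1f} degC outside "
                            f"[{cons.tm_min}, {cons.tm_max}]",
                        )
                    )

    for primer in panel.ext_primers:
        product = primer.total_len + 1
        if not win_lo <= product <= win_hi:
            findings.append(
                Finding(
                    "readable_window",
                    "error",
                    f"{primer.rsid}: product of {product} nt outside readable "
                    f"window [{win_lo}, {win_hi}]",
                )
            )
        try:
            primer.check_against(panel.target(primer.rsid), panel.dye_map)
        except (ValidationError, KeyError) as exc:
            findings.append(Finding("dye_validity", "error", str(exc)))

    gap_severity = "error" if mode == "design" else "warning"
    primers = panel.ext_primers
    for i in range(len(primers)):
        for j in range(i + 1, len(primers)):
            a, b = primers[i], primers[j]
            if not a.dye_pair & b.dye_pair:
                continue
            gap = abs(a.total_len - b.total_len)
            if gap < cons.same_dye_min_gap:
                tier = (
                    "below empirical resolution floor"
                    if gap < cons.empirical_min_gap
                    else "below design stagger"
                )
                findings.append(
                    Finding(
                        "same_dye_gap",
                        gap_severity,
                        f"{a.rsid} ({a.total_len} nt) vs {b.rsid} "
                        f"({b.total_len} nt): same-dye gap {gap} nt {tier} "
                        f"(need >= {cons.same_dye_min_gap})",
                    )
                )
    return PanelReport(mode=mode, findings=findings)


__all__ = [
    "ENZYME_PATTERNS",
    "Finding",
    "PanelReport",
    "RflpAssay",
    "check_panel",
    "digest_fragments",
    "is_palindromic",
    "rflp_differential",
]
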