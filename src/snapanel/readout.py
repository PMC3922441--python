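"""Electropherogram simulation and peak-to-genotype decoding.

A single-base extension product is one nucleotide longer than its primer;
its apparent size on the capillary drifts with the dye's molecular mass and
the polymer, which the affine per-dye MobilityModel captures.  Decoding
assigns each observed peak to the allele whose predicted size and dye it
matches: a heterozygote shows two supported alleles, a homozygote one, and
unassignable peaks are flagged non-specific but never change a call.
Genotypes are always reported as plus-strand allele pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ExtensionPrimer, PanelDesign, SnpTarget
from .errors import ValidationError

PEAK_COLUMNS = ["sample", "dye", "size_nt", "height"]


@dataclass
class MobilityModel:
    """Per-dye affine map from nominal product size to observed size."""

    params: dict[str, tuple[float, float]] = field(default_factory=dict)
    # params[dye] = (offset_nt, slope); missing dyes are identity

    def __post_init__(self):
        for dye, (offset, slope) in self.params.items():
            if slope <= 0:
                raise ValidationError(
                    f"mobility slope for {dye} must be > 0 (monotonicity)"
                )

    def predict(self, dye: str, nominal: float) -> float:
        offset, slope = self.params.get(dye, (0.0, 1.0))
        return offset + slope * nominal

    @classmethod
    def identity(cls) -> "MobilityModel":
        return cls({})


def expected_product_size(
    primer: ExtensionPrimer, mobility: Optional[MobilityModel] = None
) -> dict[str, float]:
    """Predicted observed size per allele ('ref'/'alt').

    Nominal product size is total primer length + 1 (one ddNTP); the two
    alleles share the nominal size but may separate through dye-specific
    mobility.
    """
    mobility = mobility or MobilityModel.identity()
    nominal = primer.total_len + 1
    return {
        "ref": mobility.predict(primer.dye_ref, nominal),
        "alt": mobility.predict(primer.dye_alt, nominal),
    }


def simulate_peaks(
    panel: PanelDesign,
    genotypes: dict[str, tuple[str, str]],
    noise_sd: float = 0.0,
    height_mean: float = 1000.0,
    height_sd: float = 100.0,
    nonspecific: int = 0,
    seed: int = 0,
    sample: str = "sim",
) -> pd.DataFrame:
    """Simulate a peak table for the panel under given plus-strand genotypes.

    One peak per carried allele per SNP (two for heterozygotes, one for
    homozygotes) at the mobility-predicted size plus Gaussian jitter, plus
    ``nonspecific`` low-height peaks uniform over the readable window.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    mobility = panel.mobility or MobilityModel.identity()
    rows = []
    for target in panel.targets:
        try:
            gt = genotypes[target.rsid]
        except KeyError:
            raise ValidationError(f"no genotype supplied for {target.rsid}")
        primer = panel.primer(target.rsid)
        expected = expected_product_size(primer, mobility)
        allele_info = {
            target.ref_allele: ("ref", primer.dye_ref),
            target.alt_allele: ("alt", primer.dye_alt),
        }
        for allele in sorted(set(gt)):
            if allele not in allele_info:
                raise ValidationError(
                    f"{target.rsid}: allele {allele!r} not in "
                    f"({target.ref_allele}, {target.alt_allele})"
                )
            which, dye = allele_info[allele]
            size = expected[which] + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
            height = max(1.0, rng.normal(height_mean, height_sd))
            rows.append((sample, dye, float(size), float(height)))
    win_lo, win_hi = panel.constraints.readable_window
    dyes = sorted(panel.dye_map.colours())
    for _ in range(nonspecific):
        size = rng.uniform(win_lo, win_hi)
        dye = dyes[rng.integers(len(dyes))]
        height = height_mean * rng.uniform(0.02, 0.08)
        rows.append((sample, dye, float(size), float(height)))
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


@dataclass
class GenotypeCall:
    """Decoded genotype for one SNP, reported on the plus strand."""

    rsid: str
    genotype: Optional[tuple[str, str]]  # unordered plus-strand pair, or None
    status: str  # hom_ref | hom_alt | het | no_call
    supporting_peaks: list[int] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.status not in ("hom_ref", "hom_alt", "het", "no_call"):
            raise ValidationError(f"bad call status {self.status!r}")
        if self.status == "het" and (
            self.genotype is None or self.genotype[0] == self.genotype[1]
        ):
            raise ValidationError("het call must carry two distinct alleles")
        if self.status.startswith("hom") and (
            self.genotype is None or self.genotype[0] != self.genotype[1]
        ):
            raise ValidationError("hom call must carry one allele twice")


@dataclass
class CallResult:
    """All per-SNP calls plus indices of peaks assigned to no allele."""

    calls: list[GenotypeCall]
    nonspecific_peaks: list[int] = field(default_factory=list)


def call_genotypes(
    panel: PanelDesign,
    peaks: pd.DataFrame,
    size_tol: float = 1.0,
    het_ratio_min: float = 0.15,
) -> CallResult:
    """Decode a peak table into per-SNP genotype calls.

    A peak supports an allele iff its dye matches and its observed size is
    within ``size_tol`` of the mobility-predicted size.  Both alleles
    supported with minor/major height >= ``het_ratio_min`` -> het; both
    supported below that ratio -> hom for the taller allele with an
    'imbalance' flag; one supported -> hom; none -> no_call.  Peaks
    supporting no allele anywhere are flagged non-specific.  Calls are
    independent of peak-table row order.
    """
    if size_tol <= 0:
        raise ValidationError("size_tol must be > 0")
    mobility = panel.mobility or MobilityModel.identity()
    sizes = peaks["size_nt"].to_numpy(dtype=float)
    dyes = peaks["dye"].to_numpy(dtype=object)
    heights = peaks["height"].to_numpy(dtype=float)
    order = np.lexsort((peaks.index.to_numpy(), sizes))  # row-order invariance
    assigned = np.zeros(len(peaks), dtype=bool)
    win_lo, win_hi = panel.constraints.readable_window

    calls = []
    for target in panel.targets:
        primer = panel.primer(target.rsid)
        expected = expected_product_size(primer, mobility)
        flags: list[str] = []
        support: dict[str, Optional[int]] = {}
        for which, allele, dye in (
            ("ref", target.ref_allele, primer.dye_ref),
            ("alt", target.alt_allele, primer.dye_alt),
        ):
            exp = expected[which]
            if not win_lo <= exp <= win_hi:
                flags.append(f"off-window:{which}")
            idx = [
                int(i)
                for i in order
                if dyes[i] == dye and abs(sizes[i] - exp) <= size_tol
            ]
            if len(idx) > 1:
                flags.append(f"ambiguous:{which}")
            if idx:
                best = max(idx, key=lambda i: (heights[i], -i))
                support[allele] = best
                for i in idx:
                    assigned[i] = True
            else:
                support[allele] = None
        ref_i = support[target.ref_allele]
        alt_i = support[target.alt_allele]
        if ref_i is not None and alt_i is not None:
            h_ref, h_alt = heights[ref_i], heights[alt_i]
            ratio = min(h_ref, h_alt) / max(h_ref, h_alt)
            if ratio >= het_ratio_min:
                calls.append(
                    GenotypeCall(
                        rsid=target.rsid,
                        genotype=(target.ref_allele, target.alt_allele),
                        status="het",
                        supporting_peaks=sorted((ref_i, alt_i)),
                        flags=flags,
                    )
                )
            else:
                flags.append("imbalance")
                major = target.ref_allele if h_ref >= h_alt else target.alt_allele
                status = "hom_ref" if major == target.ref_allele else "hom_alt"
                calls.append(
                    GenotypeCall(
                        rsid=target.rsid,
                        genotype=(major, major),
                        status=status,
                        supporting_peaks=[ref_i if h_ref >= h_alt else alt_i],
                        flags=flags,
                    )
                )
        elif ref_i is not None or alt_i is not None:
            allele = target.ref_allele if ref_i is not None else target.alt_allele
            idx = ref_i if ref_i is not None else alt_i
            calls.append(
                GenotypeCall(
                    rsid=target.rsid,
                    genotype=(allele, allele),
                    status="hom_ref" if allele == target.ref_allele else "hom_alt",
                    supporting_peaks=[idx],
                    flags=flags,
                )
            )
        else:
            flags.append("no-supporting-peak")
            calls.append(
                GenotypeCall(
                    rsid=target.rsid,
                    genotype=None,
                    status="no_call",
                    supporting_peaks=[],
                    flags=flags,
                )
            )
    nonspecific = [int(i) for i in range(len(peaks)) if not assigned[i]]
    return CallResult(calls=calls, nonspecific_peaks=nonspecific)


@dataclass
class MobilityFit:
    """Fitted mobility model plus per-dye residuals and warnings."""

    model: MobilityModel
    residuals: dict[str, list[float]]
    warnings: list[str] = field(default_factory=list)


def fit_mobility(
    observations: Sequence[tuple[ExtensionPrimer, str, float]]
) -> MobilityFit:
    """Least-squares per-dye affine fit of observed vs nominal product size.

    Each observation is (primer, 'ref'|'alt', observed size).  Dyes with
    >= 2 distinct nominal sizes get offset+slope; a single observation (or
    a single distinct nominal size) gets an offset-only fit; dyes with no
    observations stay identity with a warning.
    """
    by_dye: dict[str, list[tuple[float, float]]] = {}
    for primer, which, observed in observations:
        if which not in ("ref", "alt"):
            raise ValidationError(f"allele label must be 'ref' or 'alt', got {which!r}")
        dye = primer.dye_ref if which == "ref" else primer.dye_alt
        by_dye.setdefault(dye, []).append((primer.total_len + 1, float(observed)))
    params: dict[str, tuple[float, float]] = {}
    residuals: dict[str, list[float]] = {}
    warnings: list[str] = []
    for dye, obs in by_dye.items():
        x = np.array([o[0] for o in obs], dtype=float)
        y = np.array([o[1] for o in obs], dtype=float)
        if len(obs) >= 2 and len(set(x.tolist())) >= 2:
            A = np.vstack([np.ones_like(x), x]).T
            (offset, slope), *_ = np.linalg.lstsq(A, y, rcond=None)
        else:
            offset, slope = float(np.mean(y - x)), 1.0
            warnings.append(f"{dye}: offset-only fit ({len(obs)} observation(s))")
        params[dye] = (float(offset), float(slope))
        residuals[dye] = (y - (offset + slope * x)).tolist()
    return MobilityFit(MobilityModel(params), residuals, warnings)


def genotype_space(targets: Sequence[SnpTarget]) -> dict[str, int]:
    """Counts of distinct per-SNP genotype classes across a panel: each
    biallelic SNP contributes one heterozygous and two homozygous classes,
    and peak counts range from n (all hom) to 2n (all het)."""
    n = len(targets)
    return {
        "het_classes": n,
        "hom_classes": 2 * n,
        "min_peaks": n,
        "max_peaks": 2 * n,
    }


__all__ = [
    "CallResult",
    "GenotypeCall",
    "MobilityFit",
    "MobilityModel",
    "PEAK_COLUMNS",
    "call_genotypes",
    "expected_product_size",
    "fit_mobility",
    "genotype_space",
    "simulate_peaks",
]
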