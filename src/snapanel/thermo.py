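"""Melting-temperature estimation and combinatorial primer screening.

Tm estimation delegates to Biopython's MeltingTemp: the Wallace rule
(2(A+T) + 4(G+C)) as a cheap closed-form mode, and the unified
nearest-neighbour parameter set with a configurable monovalent-salt
correction as the default.  Dimer and hairpin screening are exact
complementary-run scans, not free-energy folds: stable secondary structure
is flagged by the length of the longest Watson-Crick run, which is the
quantity the length thresholds below act on.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

from .core import _check_alphabet, reverse_complement
from .errors import ValidationError

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass(frozen=True)
class TmParams:
    """Parameters for melting-temperature estimation.

    method: 'wallace' or 'nearest_neighbor'.
    salt_mM: monovalent cation concentration (mM).
    oligo_nM: oligonucleotide concentration (nM), primer in excess.
    """

    method: str = "nearest_neighbor"
    salt_mM: float = 50.0
    oligo_nM: float = 250.0

    def __post_init__(self):
        if self.method not in ("wallace", "nearest_neighbor"):
            raise ValidationError(f"unknown Tm method {self.method!r}")
        if self.salt_mM <= 0 or self.oligo_nM <= 0:
            raise ValidationError("concentrations must be > 0")


@dataclass(frozen=True)
class ScreenThresholds:
    """Secondary-structure screen thresholds (lengths in bp).

    A primer fails when its hairpin stem reaches max_hairpin_stem or a
    3'-anchored self-duplex run reaches max_dimer_run_3p; cross-dimer runs
    of max_dimer_run_3p or more anchored at a 3' end mark two primers as
    incompatible in one reaction.
    """

    max_hairpin_stem: int = 7
    max_dimer_run_3p: int = 7
    min_hairpin_loop: int = 3
    min_hairpin_stem: int = 3


@dataclass(frozen=True)
class DuplexReport:
    """Longest complementary run between two primers."""

    max_run: int
    run_3p: int  # longest run that includes either sequence's 3' terminus

    def __post_init__(self):
        if self.run_3p > self.max_run:
            raise ValidationError("3'-anchored run cannot exceed max run")


def melting_temperature(seq: str, params: TmParams | None = None) -> float:
    """Estimated melting temperature in degC.

    Wallace rule for quick length-class checks (valid from 2 nt); the
    unified nearest-neighbour estimate (Allawi & SantaLucia parameters,
    salt correction 0.368*(N-1)*ln[Na+]) for design-grade scoring
    (requires >= 8 nt).
    """
    params = params or TmParams()
    seq = _check_alphabet(seq, allow_n=False)
    if params.method == "wallace":
        if len(seq) < 2:
            raise ValidationError("sequence too short for Wallace Tm")
        return float(_mt.Tm_Wallace(seq))
    if len(seq) < 8:
        raise ValidationError("sequence too short for nearest-neighbour Tm")
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=_mt.DNA_NN3,
            Na=params.salt_mM,
            dnac1=params.oligo_nM,
            dnac2=0,
            saltcorr=5,
        )
    )


def _complementary_runs(seq_a: str, seq_b: str):
    """Yield (run_length, i_end_a, j_end_rcb) for all ungapped antiparallel
    alignments, expressed as runs of equality between seq_a and
    reverse_complement(seq_b)."""
    rcb = reverse_complement(seq_b)
    la, lb = len(seq_a), len(rcb)
    for offset in range(-(lb - 1), la):
        run = 0
        i = max(0, offset)
        j = i - offset
        while i < la and j < lb:
            if seq_a[i] == rcb[j]:
                run += 1
                yield run, i, j
            else:
                run = 0
            i += 1
            j += 1


def duplex_screen(seq_a: str, seq_b: str) -> DuplexReport:
    """Longest contiguous Watson-Crick run over all ungapped antiparallel
    alignments of seq_a against seq_b, plus the longest such run touching
    either sequence's 3' terminus."""
    seq_a = _check_alphabet(seq_a, allow_n=False)
    seq_b = _check_alphabet(seq_b, allow_n=False)
    if not seq_a or not seq_b:
        raise ValidationError("duplex_screen requires non-empty sequences")
    max_run = 0
    run_3p = 0
    la = len(seq_a)
    for run, i, j in _complementary_runs(seq_a, seq_b):
        max_run = max(max_run, run)
        # seq_a 3' terminus = index la-1; seq_b 3' terminus maps to index 0
        # of its reverse complement, i.e. the run must extend back to j=0.
        if i == la - 1 or j - run + 1 == 0:
            run_3p = max(run_3p, run)
    return DuplexReport(max_run=max_run, run_3p=run_3p)


def hairpin_screen(seq: str, min_stem: int = 3, min_loop: int = 3) -> int:
    """Longest self-complementary hairpin stem with loop >= min_loop.

    Exhaustive scan over all (stem start, stem end, stem length) triples;
    returns 0 when no stem of at least min_stem exists.
    """
    if min_stem < 3 or min_loop < 3:
        raise ValidationError("min_stem and min_loop must both be >= 3")
    seq = _check_alphabet(seq, allow_n=False)
    n = len(seq)
    best = 0
    # A stem is a run of pairings (i, m), (i+1, m-1), ... between the 5'
    # arm moving right and the 3' arm moving left; runs live on diagonals
    # of the pairing matrix (constant i + m).  Walk each diagonal once and,
    # for each maximal run, trim inner pairs until the innermost loop
    # reaches min_loop (each trimmed pair widens the loop by 2).
    for diag in range(2 * n - 1):  # diag = i + m
        run = 0
        i = max(0, diag - (n - 1))
        m = diag - i
        while i < n and m >= 0:
            if m > i and (seq[i], seq[m]) in _PAIRS:
                run += 1
                loop = m - i - 1
                usable = run - max(0, -(-(min_loop - loop) // 2))  # ceil
                if usable >= min_stem:
                    best = max(best, usable)
            else:
                run = 0
            i += 1
            m -= 1
    return best


def screen_primer(seq: str, thresholds: ScreenThresholds | None = None) -> dict:
    """Run hairpin and self-dimer screens; returns verdicts and statistics."""
    th = thresholds or ScreenThresholds()
    stem = hairpin_screen(seq, min_stem=th.min_hairpin_stem, min_loop=th.min_hairpin_loop)
    self_dup = duplex_screen(seq, seq)
    return {
        "hairpin_stem": stem,
        "self_dimer_run_3p": self_dup.run_3p,
        "self_dimer_max_run": self_dup.max_run,
        "hairpin_pass": stem < th.max_hairpin_stem,
        "dimer_pass": self_dup.run_3p < th.max_dimer_run_3p,
    }


def cross_dimer_conflict(
    seq_a: str, seq_b: str, thresholds: ScreenThresholds | None = None
) -> bool:
    """True when two primers form a 3'-anchored cross-dimer long enough to
    compete in one reaction."""
    th = thresholds or ScreenThresholds()
    return duplex_screen(seq_a, seq_b).run_3p >= th.max_dimer_run_3p


__all__ = [
    "DuplexReport",
    "ScreenThresholds",
    "TmParams",
    "cross_dimer_conflict",
    "duplex_screen",
    "hairpin_screen",
    "melting_temperature",
    "screen_primer",
]
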