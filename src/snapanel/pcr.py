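"""Flanking PCR primer search, in-silico PCR, uniqueness screening, and
multiplex reaction partitioning.

The candidate search enumerates every legal (forward, reverse) primer pair
around the targets, filters on length/Tm/secondary-structure rules, and
ranks deterministically.  Genome uniqueness is an exact-match scan over
user-supplied sequences (a network-free stand-in with the same contract as
a BLAST screen; a real aligner can be wired in through the same
interface).  The A/B reaction split is greedy colouring of a cross-dimer
conflict graph.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .core import (
    DesignConstraints,
    PcrPrimerPair,
    ReferenceContext,
    SnpTarget,
    reverse_complement,
)
from .errors import CoverageError, ValidationError
from .thermo import (
    ScreenThresholds,
    TmParams,
    cross_dimer_conflict,
    duplex_screen,
    hairpin_screen,
    melting_temperature,
)


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on the plus strand, 1-based inclusive."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PcrCandidate:
    """One scored forward/reverse primer pair enclosing the target SNPs."""

    fwd_seq: str
    rev_seq: str
    amplicon: Amplicon
    score: float
    tm_fwd: float
    tm_rev: float
    report: dict = field(default_factory=dict)


@dataclass
class CandidateSearch:
    """Ranked passing candidates plus a per-rule failure tally."""

    candidates: list[PcrCandidate]
    failure_tally: Counter

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self):
        return len(self.candidates)


def _primer_ok(
    seq: str,
    constraints: DesignConstraints,
    tm_params: TmParams,
    thresholds: ScreenThresholds,
    tally: Counter,
) -> Optional[tuple[float, float]]:
    """Return (tm, penalty) when the primer passes all per-primer rules."""
    tm = melting_temperature(seq, tm_params)
    if not constraints.tm_min <= tm <= constraints.tm_max:
        tally["tm_window"] += 1
        return None
    stem = hairpin_screen(
        seq, min_stem=thresholds.min_hairpin_stem, min_loop=thresholds.min_hairpin_loop
    )
    if stem >= thresholds.max_hairpin_stem:
        tally["hairpin"] += 1
        return None
    self_run = duplex_screen(seq, seq).run_3p
    if self_run >= thresholds.max_dimer_run_3p:
        tally["self_dimer"] += 1
        return None
    return tm, float(stem + self_run)


def enumerate_pcr_candidates(
    targets: Sequence[SnpTarget],
    context: ReferenceContext,
    constraints: DesignConstraints | None = None,
    max_amplicon: int = 650,
    tm_params: TmParams | None = None,
    thresholds: ScreenThresholds | None = None,
    max_candidates: int = 50,
) -> CandidateSearch:
    """Enumerate and rank flanking primer pairs around a group of SNPs.

    Every candidate amplicon encloses all target positions strictly inside
    it, clear of both primer footprints; both primers respect the length
    bounds and pass Tm/hairpin/self-dimer screens.  Ranking is by
    score = |Tm_fwd - Tm_mid| + |Tm_rev - Tm_mid| + structure penalties,
    with ties broken by smaller amplicon then leftmost start.
    """
    constraints = constraints or DesignConstraints()
    tm_params = tm_params or TmParams()
    thresholds = thresholds or ScreenThresholds()
    if not targets:
        raise ValidationError("no targets given")
    positions = [t.pos for t in targets]
    lo, hi = min(positions), max(positions)
    if not context.covers(lo - max_amplicon, hi + max_amplicon):
        raise CoverageError(
            f"window must extend >= {max_amplicon} bp beyond every target "
            f"(targets span {lo}-{hi}, window "
            f"{context.window_start}-{context.window_end})"
        )
    span = hi - lo + 1
    if span + 2 * constraints.pcr_len_min > max_amplicon:
        raise CoverageError(
            f"targets spanning {span} bp cannot be enclosed by primers inside "
            f"a {max_amplicon} bp amplicon"
        )
    tm_mid = (constraints.tm_min + constraints.tm_max) / 2.0
    tally: Counter = Counter()

    # Per-primer pre-filter: forward primers must end 5' of the leftmost
    # SNP, reverse primers must start 3' of the rightmost SNP.
    fwd_ok: list[tuple[int, int, str, float, float]] = []  # (start, len, seq, tm, pen)
    rev_ok: list[tuple[int, int, str, float, float]] = []  # (end, len, seq, tm, pen)
    for length in range(constraints.pcr_len_min, constraints.pcr_len_max + 1):
        for start in range(lo - max_amplicon + 1, lo - length + 1):
            seq = context.slice(start, start + length - 1)
            if "N" in seq:
                tally["ambiguous_base"] += 1
                continue
            res = _primer_ok(seq, constraints, tm_params, thresholds, tally)
            if res:
                fwd_ok.append((start, length, seq, res[0], res[1]))
        for end in range(hi + length, hi + max_amplicon):
            if end > context.window_end:
                break
            plus = context.slice(end - length + 1, end)
            if "N" in plus:
                tally["ambiguous_base"] += 1
                continue
            seq = reverse_complement(plus)
            res = _primer_ok(seq, constraints, tm_params, thresholds, tally)
            if res:
                rev_ok.append((end, length, seq, res[0], res[1]))

    # Pair primers in ascending order of their summed per-primer score.
    # The cross-dimer term is non-negative, so once a partial score
    # exceeds the current max_candidates-th best total score no later
    # pair can enter the ranking — prune without losing exactness.
    fwd_ok.sort(key=lambda p: abs(p[3] - tm_mid) + p[4])
    rev_ok.sort(key=lambda p: abs(p[3] - tm_mid) + p[4])
    candidates: list[PcrCandidate] = []
    scores: list[float] = []
    bound = float("inf")
    for fs, fl, fseq, ftm, fpen in fwd_ok:
        f_part = abs(ftm - tm_mid) + fpen
        if rev_ok and f_part + abs(rev_ok[0][3] - tm_mid) + rev_ok[0][4] > bound:
            break
        for re_, rl, rseq, rtm, rpen in rev_ok:
            partial = f_part + abs(rtm - tm_mid) + rpen
            if partial > bound:
                break
            amp_len = re_ - fs + 1
            if amp_len > max_amplicon:
                continue
            if fs + fl - 1 >= lo or re_ - rl + 1 <= hi:
                continue  # a SNP would sit inside a primer footprint
            cross = duplex_screen(fseq, rseq).run_3p
            if cross >= thresholds.max_dimer_run_3p:
                tally["cross_dimer"] += 1
                continue
            score = partial + cross
            scores.append(score)
            if len(scores) >= max_candidates:
                scores.sort()
                bound = scores[max_candidates - 1]
            candidates.append(
                PcrCandidate(
                    fwd_seq=fseq,
                    rev_seq=rseq,
                    amplicon=Amplicon(fs, re_),
                    score=score,
                    tm_fwd=ftm,
                    tm_rev=rtm,
                    report={
                        "fwd_penalty": fpen,
                        "rev_penalty": rpen,
                        "cross_dimer_run_3p": cross,
                    },
                )
            )
    candidates.sort(
        key=lambda c: (c.score, c.amplicon.length, c.amplicon.start, c.amplicon.end)
    )
    return CandidateSearch(candidates[:max_candidates], tally)


def in_silico_pcr(
    fwd_seq: str, rev_seq: str, context: ReferenceContext
) -> list[Amplicon]:
    """All products where fwd matches the plus strand and rev the minus
    strand exactly, with the forward site 5' of the reverse site."""
    fwd_seq = fwd_seq.upper()
    rev_seq = rev_seq.upper()
    if len(fwd_seq) < 12 or len(rev_seq) < 12:
        raise ValidationError("primers must be >= 12 nt for in-silico PCR")
    seq = context.sequence
    rev_site = reverse_complement(rev_seq)  # plus-strand image of rev primer

    def _occurrences(needle: str) -> list[int]:
        out, i = [], seq.find(needle)
        while i != -1:
            out.append(i)
            i = seq.find(needle, i + 1)
        return out

    products = []
    fwd_starts = _occurrences(fwd_seq)
    rev_starts = _occurrences(rev_site)
    for fs in fwd_starts:
        for rs in rev_starts:
            re_ = rs + len(rev_seq) - 1
            if fs <= rs and fs + len(fwd_seq) - 1 <= re_:
                products.append(
                    Amplicon(
                        start=context.window_start + fs,
                        end=context.window_start + re_,
                    )
                )
    products.sort(key=lambda a: (a.start, a.end))
    return products


def uniqueness_scan(primer_seq: str, sequences: Iterable[str]) -> int:
    """Exact occurrence count of the primer and its reverse complement
    across a sequence set.  Both orientations always count, so a primer
    equal to its own reverse complement present once scores 2."""
    primer_seq = primer_seq.upper()
    if len(primer_seq) < 12:
        raise ValidationError("primer must be >= 12 nt for uniqueness scan")
    rc = reverse_complement(primer_seq)
    count = 0
    for raw in sequences:
        seq = raw.upper()
        for needle in (primer_seq, rc):
            i = seq.find(needle)
            while i != -1:
                count += 1
                i = seq.find(needle, i + 1)
    return count


@dataclass
class ReactionAssignment:
    """Mapping of each PCR pair (by index) to a reaction label."""

    labels: list[str]
    n_reactions: int

    def by_label(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, lab in enumerate(self.labels):
            out.setdefault(lab, []).append(i)
        return out


def _label(i: int) -> str:
    # A, B, ..., Z, AA, AB, ...
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = chr(ord("A") + r) + out
    return out


def partition_reactions(
    pairs: Sequence[PcrPrimerPair],
    conflict: Optional[Callable[[PcrPrimerPair, PcrPrimerPair], bool]] = None,
    thresholds: ScreenThresholds | None = None,
) -> ReactionAssignment:
    """Greedy graph colouring of the pair-conflict graph into reactions.

    Default conflict rule: any 3'-anchored cross-dimer run at or above the
    screen threshold between any primer of one pair and any primer of the
    other.  Vertices are coloured in order of descending conflict degree
    (ties by input order) with the lowest available label.
    """
    th = thresholds or ScreenThresholds()
    if conflict is None:

        def conflict(a: PcrPrimerPair, b: PcrPrimerPair) -> bool:
            return any(
                cross_dimer_conflict(x, y, th)
                for x in (a.fwd_seq, a.rev_seq)
                for y in (b.fwd_seq, b.rev_seq)
            )

    n = len(pairs)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if conflict(pairs[i], pairs[j]):
                adj[i][j] = adj[j][i] = True
    degree = [sum(row) for row in adj]
    order = sorted(range(n), key=lambda i: (-degree[i], i))
    colour = [-1] * n
    for v in order:
        used = {colour[u] for u in range(n) if adj[v][u] and colour[u] >= 0}
        c = 0
        while c in used:
            c += 1
        colour[v] = c
    n_used = max(colour) + 1 if n else 0
    return ReactionAssignment([_label(c) for c in colour], n_used)


__all__ = [
    "Amplicon",
    "CandidateSearch",
    "PcrCandidate",
    "ReactionAssignment",
    "enumerate_pcr_candidates",
    "in_silico_pcr",
    "partition_reactions",
    "uniqueness_scan",
]
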