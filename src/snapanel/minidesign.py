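"""Extension-primer design: placement, flanking-variant conflicts, neutral
tails, and the dye-aware length-staggering solver.

A minisequencing primer must end immediately 5' of the interrogated base on
its strand, so the only design freedoms are strand, core length, and the
5' neutral tail that shifts the product's electrophoretic size.  Products
whose dyes can collide are staggered by at least ``same_dye_min_gap``
nucleotides inside the readable sizing window; the solver minimises the
longest primer and is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    DesignConstraints,
    DyeMap,
    ExtensionPrimer,
    ReferenceContext,
    SnpTarget,
    Strand,
    detected_bases,
    reverse_complement,
)
from .errors import AmbiguityError, CapacityError, CoverageError, ValidationError
from .thermo import ScreenThresholds, screen_primer

MIN_CORE_LEN = 14


def place_extension_primer(
    target: SnpTarget, context: ReferenceContext, strand: Strand, core_len: int
) -> str:
    """Genomic core of the extension primer, 5'->3' on the chosen strand.

    Plus strand: the ``core_len`` plus-strand bases ending immediately 5'
    of the SNP.  Minus strand: the reverse complement of the plus-strand
    bases immediately 3' of the SNP.
    """
    if core_len < 1:
        raise ValidationError("core length must be >= 1")
    if strand == "plus":
        lo, hi = target.pos - core_len, target.pos - 1
    elif strand == "minus":
        lo, hi = target.pos + 1, target.pos + core_len
    else:
        raise ValidationError(f"bad strand {strand!r}")
    if not context.covers(lo, hi):
        raise CoverageError(
            f"{target.rsid}: {strand}-strand footprint {lo}-{hi} outside window"
        )
    seq = context.slice(lo, hi)
    if "N" in seq:
        raise AmbiguityError(f"{target.rsid}: footprint contains ambiguous bases")
    return seq if strand == "plus" else reverse_complement(seq)


@dataclass
class ConflictReport:
    """Which strands a target's single-primer design is blocked on."""

    rsid: str
    plus_blocked: bool
    minus_blocked: bool
    plus_blockers: list[str] = field(default_factory=list)
    minus_blockers: list[str] = field(default_factory=list)

    @property
    def undesignable(self) -> bool:
        return self.plus_blocked and self.minus_blocked


def flanking_conflict(
    target: SnpTarget, variants: Sequence, footprint_len: int = 40
) -> ConflictReport:
    """Detect known variants inside either strand's primer footprint.

    The footprint includes the interrogated base itself, so indels that
    overlap the SNP block both strands — the situation that makes a locus
    undesignable by any single extension primer.
    """
    if footprint_len < MIN_CORE_LEN:
        raise ValidationError(f"footprint must be >= {MIN_CORE_LEN}")
    plus_lo, plus_hi = target.pos - footprint_len, target.pos
    minus_lo, minus_hi = target.pos, target.pos + footprint_len
    plus_blockers = [v.id for v in variants if v.intersects(plus_lo, plus_hi)]
    minus_blockers = [v.id for v in variants if v.intersects(minus_lo, minus_hi)]
    return ConflictReport(
        rsid=target.rsid,
        plus_blocked=bool(plus_blockers),
        minus_blocked=bool(minus_blockers),
        plus_blockers=plus_blockers,
        minus_blockers=minus_blockers,
    )


def tail_sequence(k: int, constraints: DesignConstraints | None = None) -> str:
    """Length-k neutral tail: a suffix of the master tail, poly(C)-padded
    at the 5' end once the master is exhausted."""
    constraints = constraints or DesignConstraints()
    if k < 0:
        raise ValidationError("tail length must be >= 0")
    master = constraints.master_tail.lower()
    if k <= len(master):
        return master[len(master) - k :]
    return constraints.pad_base.lower() * (k - len(master)) + master


@dataclass
class SpacingProblem:
    """Input to the dye-aware length stagger: per-primer core lengths and
    dye pairs, plus the sizing window and gap rules."""

    core_lengths: list[int]
    dye_pairs: list[frozenset]
    constraints: DesignConstraints = field(default_factory=DesignConstraints)

    def __post_init__(self):
        if len(self.core_lengths) != len(self.dye_pairs):
            raise ValidationError("core_lengths and dye_pairs must align")
        if any(c < MIN_CORE_LEN for c in self.core_lengths):
            raise ValidationError(f"core lengths must be >= {MIN_CORE_LEN}")


def solve_spacing(problem: SpacingProblem) -> list[int]:
    """Assign total primer lengths obeying the same-dye stagger rule.

    Constraints: total >= core; |total_i - total_j| >= same_dye_min_gap
    whenever primers i and j share a dye; total + 1 (the extended product)
    inside the readable window.  The maximum total is minimised; among
    minimal-makespan solutions the lexicographically smallest assignment
    in input order is returned.
    """
    n = len(problem.core_lengths)
    if n < 1:
        raise ValidationError("at least one primer required")
    cons = problem.constraints
    win_lo, win_hi = cons.readable_window
    gap = cons.same_dye_min_gap
    lows = [max(c, win_lo - 1) for c in problem.core_lengths]
    hi_total = win_hi - 1
    if any(lo > hi_total for lo in lows):
        raise CapacityError(
            f"a core of {max(problem.core_lengths)} nt cannot produce a "
            f"product inside the readable window {cons.readable_window}"
        )
    share = [
        [bool(problem.dye_pairs[i] & problem.dye_pairs[j]) for j in range(n)]
        for i in range(n)
    ]

    # Search with per-primer value domains held as bitmasks (bit v = total
    # length v is still available).  Assigning v to a primer blocks the
    # band [v-gap+1, v+gap-1] for every dye-sharing neighbour.
    budget = 2_000_000

    def band(v: int) -> int:
        lo = max(0, v - gap + 1)
        return ((1 << (v + gap - lo)) - 1) << lo

    def search(limit: int, input_order: bool) -> Optional[list[int]]:
        nonlocal budget
        full = [
            ((1 << (limit + 1)) - 1) & ~((1 << lows[i]) - 1) for i in range(n)
        ]
        totals: list[Optional[int]] = [None] * n

        def dfs(remaining: list[int], domains: list[int]) -> bool:
            nonlocal budget
            if not remaining:
                return True
            budget -= 1
            if budget <= 0:
                raise CapacityError(
                    f"spacing search budget exhausted on {n} primers; "
                    "split the panel into per-locus assays"
                )
            if input_order:
                idx = remaining[0]
            else:  # most-constrained-first for fast feasibility proofs
                idx = min(remaining, key=lambda i: (domains[i].bit_count(), i))
            rest = [i for i in remaining if i != idx]
            dom = domains[idx]
            while dom:
                v = (dom & -dom).bit_length() - 1  # smallest available value
                dom &= dom - 1
                new_domains = list(domains)
                blocked = band(v)
                dead = False
                for j in rest:
                    if share[idx][j]:
                        new_domains[j] &= ~blocked
                        if not new_domains[j]:
                            dead = True
                            break
                if not dead:
                    totals[idx] = v
                    if dfs(rest, new_domains):
                        return True
                    totals[idx] = None
            return False

        if dfs(list(range(n)), full):
            return [int(t) for t in totals]  # type: ignore[arg-type]
        return None

    # Primers sharing one colour are pairwise conflicting (a clique); the
    # optimal single-clique schedule is a tight makespan lower bound.
    colours = set().union(*problem.dye_pairs) if n else set()
    lb = max(lows)
    for colour in colours:
        member_lows = sorted(
            lows[i] for i in range(n) if colour in problem.dye_pairs[i]
        )
        t = None
        for c in member_lows:
            t = c if t is None else max(c, t + gap)
        if t is not None:
            lb = max(lb, t)

    # Token bound: two primers closer than the gap must have disjoint dye
    # pairs, so a solution packs at most (max #disjoint pairings) primer
    # pairs into shared slots; the remaining tokens sit >= gap apart.
    from collections import Counter as _Counter

    class_counts = _Counter(problem.dye_pairs)
    pairings = 0
    seen = set()
    for cls, cnt in class_counts.items():
        if cls in seen:
            continue
        partners = [
            (c2, n2)
            for c2, n2 in class_counts.items()
            if c2 is not cls and not (cls & c2)
        ]
        if partners:
            c2, n2 = partners[0]
            pairings += min(cnt, n2)
            seen.add(c2)
        seen.add(cls)
    tokens = n - pairings
    lb = max(lb, min(lows) + gap * (tokens - 1))
    # And the sorted-lows capacity bound: the i-th smallest total is at
    # least the i-th smallest core, and totals two apart differ >= gap.
    sorted_lows = sorted(lows)
    for i, low in enumerate(sorted_lows):
        lb = max(lb, low + gap * ((n - 1 - i) // 2))

    for limit in range(lb, hi_total + 1):
        if search(limit, input_order=False) is not None:
            # minimal makespan found; now the lexicographically smallest
            # assignment in input order within that makespan
            sol = search(limit, input_order=True)
            assert sol is not None
            return sol
    raise CapacityError(
        f"{n} primers cannot be staggered inside the readable window "
        f"{cons.readable_window} with a {gap} nt same-dye gap"
    )


@dataclass
class PanelBuildResult:
    """Primers successfully designed plus per-target failure reports."""

    primers: list[ExtensionPrimer]
    failures: dict[str, str] = field(default_factory=dict)
    warnings: dict[str, str] = field(default_factory=dict)


def build_extension_panel(
    targets: Sequence[SnpTarget],
    context: ReferenceContext | dict[str, ReferenceContext],
    constraints: DesignConstraints | None = None,
    dye_map: DyeMap | None = None,
    thresholds: ScreenThresholds | None = None,
    core_len_range: tuple[int, int] = (17, 24),
    footprint_len: int = 40,
) -> PanelBuildResult:
    """Design one extension primer per target, end to end.

    Strand policy: prefer a strand that is not blocked by known flanking
    variants and whose shortest core passes the hairpin/self-dimer
    screens; ties go to plus.  Core length is the smallest in
    ``core_len_range`` passing the screens (falling back to the shortest
    core with a warning when none passes).  Totals come from
    ``solve_spacing``; tails from ``tail_sequence``.  Deterministic.
    """
    constraints = constraints or DesignConstraints()
    dye_map = dye_map or DyeMap()
    thresholds = thresholds or ScreenThresholds()

    def ctx_for(t: SnpTarget) -> ReferenceContext:
        if isinstance(context, dict):
            return context[t.chrom]
        return context

    chosen: list[tuple[SnpTarget, Strand, str]] = []
    failures: dict[str, str] = {}
    warnings: dict[str, str] = {}
    for t in targets:
        ctx = ctx_for(t)
        report = flanking_conflict(t, ctx.known_variants, footprint_len)
        if report.undesignable:
            failures[t.rsid] = (
                "undesignable by single primer: both strands blocked by "
                + ",".join(sorted(set(report.plus_blockers + report.minus_blockers)))
            )
            continue
        options: list[tuple[int, int, Strand, str]] = []  # (not_pass, order, strand, core)
        for order, strand in enumerate(("plus", "minus")):
            if (strand == "plus" and report.plus_blocked) or (
                strand == "minus" and report.minus_blocked
            ):
                continue
            best_core: Optional[str] = None
            passing = False
            for core_len in range(core_len_range[0], core_len_range[1] + 1):
                try:
                    core = place_extension_primer(t, ctx, strand, core_len)
                except (CoverageError, AmbiguityError):
                    continue
                if best_core is None:
                    best_core = core
                scr = screen_primer(core, thresholds)
                if scr["hairpin_pass"] and scr["dimer_pass"]:
                    best_core, passing = core, True
                    break
            if best_core is not None:
                options.append((0 if passing else 1, order, strand, best_core))
        if not options:
            failures[t.rsid] = "no placeable core on any unblocked strand"
            continue
        options.sort()
        not_pass, _, strand, core = options[0]
        if not_pass:
            warnings[t.rsid] = "no core length passed secondary-structure screens"
        chosen.append((t, strand, core))

    if not chosen:
        return PanelBuildResult([], failures, warnings)

    dye_pairs = []
    for t, strand, core in chosen:
        ref_b, alt_b = detected_bases(t, strand)
        dye_pairs.append(frozenset((dye_map[ref_b], dye_map[alt_b])))
    problem = SpacingProblem(
        core_lengths=[len(c) for _, _, c in chosen],
        dye_pairs=dye_pairs,
        constraints=constraints,
    )
    totals = solve_spacing(problem)

    primers = []
    for (t, strand, core), total in zip(chosen, totals):
        ref_b, alt_b = detected_bases(t, strand)
        primers.append(
            ExtensionPrimer(
                rsid=t.rsid,
                strand=strand,
                core_seq=core,
                tail_seq=tail_sequence(total - len(core), constraints),
                detected_base_ref=ref_b,
                detected_base_alt=alt_b,
                dye_ref=dye_map[ref_b],
                dye_alt=dye_map[alt_b],
            )
        )
    return PanelBuildResult(primers, failures, warnings)


__all__ = [
    "ConflictReport",
    "MIN_CORE_LEN",
    "PanelBuildResult",
    "SpacingProblem",
    "build_extension_panel",
    "flanking_conflict",
    "place_extension_primer",
    "solve_spacing",
    "tail_sequence",
]
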