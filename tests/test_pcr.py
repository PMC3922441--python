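"""PCR candidate search, in-silico PCR, uniqueness scan, reaction split."""

import itertools
import random
from types import SimpleNamespace

import pytest

from snapanel.core import DesignConstraints, ReferenceContext, SnpTarget, reverse_complement
from snapanel.errors import CoverageError
from snapanel.pcr import (
    enumerate_pcr_candidates,
    in_silico_pcr,
    partition_reactions,
    uniqueness_scan,
)
from snapanel.thermo import ScreenThresholds, TmParams, duplex_screen, hairpin_screen, melting_temperature


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


WIDE = DesignConstraints(tm_min=30.0, tm_max=90.0)
WALLACE = TmParams(method="wallace")


def test_candidates_enclose_snp_and_respect_bounds():
    rng = random.Random(1)
    seq = _random_seq(rng, 400)
    ctx = ReferenceContext("c", 1, seq)
    target = SnpTarget("rs1", "c", 200, seq[199], "A" if seq[199] != "A" else "C")
    search = enumerate_pcr_candidates(
        [target], ctx, constraints=WIDE, max_amplicon=120, tm_params=WALLACE
    )
    assert search.candidates
    for cand in search:
        amp = cand.amplicon
        assert amp.length <= 120
        assert amp.start < 200 < amp.end
        # the SNP is clear of both primer footprints
        assert amp.start + len(cand.fwd_seq) - 1 < 200
        assert amp.end - len(cand.rev_seq) + 1 > 200
        assert 17 <= len(cand.fwd_seq) <= 29
        assert 17 <= len(cand.rev_seq) <= 29


def test_two_distant_snps_with_small_amplicon_is_coverage_error():
    rng = random.Random(2)
    ctx = ReferenceContext("c", 1, _random_seq(rng, 400))
    t1 = SnpTarget("rs1", "c", 150, "A", "C")
    t2 = SnpTarget("rs2", "c", 230, "A", "C")
    with pytest.raises(CoverageError):
        enumerate_pcr_candidates([t1, t2], ctx, constraints=WIDE, max_amplicon=60)


def _brute_force_candidates(target, ctx, constraints, max_amplicon, th):
    """Independent exhaustive enumeration with identical scoring rules."""
    tm_mid = (constraints.tm_min + constraints.tm_max) / 2.0
    pos = target.pos
    seq = ctx.sequence
    memo = {}

    def stats(s):
        if s in memo:
            return memo[s]
        memo[s] = None
        tm = melting_temperature(s, WALLACE)
        if not constraints.tm_min <= tm <= constraints.tm_max:
            return None
        stem = hairpin_screen(s)
        if stem >= th.max_hairpin_stem:
            return None
        run3 = duplex_screen(s, s).run_3p
        if run3 >= th.max_dimer_run_3p:
            return None
        memo[s] = (tm, stem + run3)
        return memo[s]

    results = []
    L = len(seq)
    for fl in range(constraints.pcr_len_min, constraints.pcr_len_max + 1):
        for fs in range(1, L - fl + 2):
            if fs + fl - 1 >= pos:
                continue
            for rl in range(constraints.pcr_len_min, constraints.pcr_len_max + 1):
                for re_ in range(pos + rl, L + 1):
                    if re_ - fs + 1 > max_amplicon:
                        continue
                    if re_ - rl + 1 <= pos:
                        continue
                    fseq = seq[fs - 1 : fs - 1 + fl]
                    rseq = reverse_complement(seq[re_ - rl : re_])
                    f = stats(fseq)
                    r = stats(rseq)
                    if f is None or r is None:
                        continue
                    cross = duplex_screen(fseq, rseq).run_3p
                    if cross >= th.max_dimer_run_3p:
                        continue
                    score = abs(f[0] - tm_mid) + abs(r[0] - tm_mid) + f[1] + r[1] + cross
                    results.append((score, re_ - fs + 1, fs, re_, fseq, rseq))
    results.sort()
    return results


def test_top_candidate_matches_brute_force_enumeration():
    rng = random.Random(4)
    seq = _random_seq(rng, 100)
    ctx = ReferenceContext("c", 1, seq)
    target = SnpTarget("rs1", "c", 50, seq[49], "A" if seq[49] != "A" else "C")
    cons = DesignConstraints(tm_min=50.0, tm_max=70.0)
    th = ScreenThresholds()
    search = enumerate_pcr_candidates(
        [target], ctx, constraints=cons, max_amplicon=40, tm_params=WALLACE,
        thresholds=th,
    )
    brute = _brute_force_candidates(target, ctx, cons, 40, th)
    assert search.candidates, "expected at least one passing candidate"
    top = search.candidates[0]
    score, amp_len, fs, re_, fseq, rseq = brute[0]
    assert (top.fwd_seq, top.rev_seq) == (fseq, rseq)
    assert top.score == pytest.approx(score)
    assert (top.amplicon.start, top.amplicon.end) == (fs, re_)


def test_in_silico_pcr_constructed_product():
    rng = random.Random(5)
    seq = _random_seq(rng, 50)
    ctx = ReferenceContext("c", 1, seq)
    fwd = seq[:18]
    rev = reverse_complement(seq[30:50])
    products = in_silico_pcr(fwd, rev, ctx)
    assert [(p.start, p.end, p.length) for p in products] == [(1, 50, 50)]
    # reverse primer absent -> no product
    assert in_silico_pcr(fwd, "ACGTACGTACGTACGT", ctx) == []


def test_in_silico_pcr_reproduces_published_amplicon(fixture_set, toy_genome):
    """The rs9389268/rs9402685 pair amplifies a single 221 bp product."""
    pair = next(
        p
        for p in fixture_set.pcr_pairs("HBS1L-MYB")
        if p.covered_rsids == ["rs9389268", "rs9402685"]
    )
    ctx = toy_genome.context(toy_genome.locus_chrom["HBS1L-MYB"])
    products = in_silico_pcr(pair.fwd_seq, pair.rev_seq, ctx)
    assert len(products) == 1
    assert products[0].length == 221


def test_all_published_pcr_primer_lengths_in_bounds(fixture_set):
    for locus in ("BCL11A", "HBS1L-MYB"):
        for pair in fixture_set.pcr_pairs(locus):
            assert 17 <= len(pair.fwd_seq) <= 29
            assert 17 <= len(pair.rev_seq) <= 29


def test_uniqueness_scan_counts_both_orientations():
    rng = random.Random(6)
    back = _random_seq(rng, 500)
    primer = "ATCGATTGCCAGTAC"
    seqs = [back[:250] + primer + back[250:]]
    assert uniqueness_scan(primer, seqs) == 1
    palindrome = "ACGTGCATATGCACGT"
    assert palindrome == reverse_complement(palindrome)
    assert uniqueness_scan(palindrome, ["TT" + palindrome + "GG"]) == 2


def test_uniqueness_scan_matches_naive_sliding_window():
    rng = random.Random(8)
    seq = _random_seq(rng, 10000)
    for _ in range(20):
        i = rng.randrange(0, 10000 - 15)
        primer = seq[i : i + 15]
        rc = reverse_complement(primer)
        naive = sum(
            seq[j : j + 15] in (primer, rc) for j in range(len(seq) - 14)
        )
        assert uniqueness_scan(primer, [seq]) == naive


def _fake_pairs(n):
    return [SimpleNamespace(idx=i) for i in range(n)]


def test_partition_no_conflicts_single_reaction():
    assignment = partition_reactions(_fake_pairs(5), conflict=lambda a, b: False)
    assert assignment.labels == ["A"] * 5
    assert assignment.n_reactions == 1


def test_partition_complete_graph_uses_n_reactions():
    assignment = partition_reactions(_fake_pairs(3), conflict=lambda a, b: True)
    assert sorted(assignment.labels) == ["A", "B", "C"]
    assert assignment.n_reactions == 3


def _chromatic_number(n, edges):
    for k in range(1, n + 1):
        for colours in itertools.product(range(k), repeat=n):
            if all(colours[u] != colours[v] for u, v in edges):
                return k
    return n


def test_greedy_colouring_within_one_of_chromatic_number():
    """Greedy reaction count <= exact chromatic number + 1 on 100 seeded
    random 6-node conflict graphs."""
    for seed in range(100):
        rng = random.Random(seed)
        edges = [
            (i, j)
            for i in range(6)
            for j in range(i + 1, 6)
            if rng.random() < 0.4
        ]
        edge_set = {frozenset(e) for e in edges}
        assignment = partition_reactions(
            _fake_pairs(6),
            conflict=lambda a, b: frozenset((a.idx, b.idx)) in edge_set,
        )
        # never two conflicting pairs in one reaction
        for u, v in edges:
            assert assignment.labels[u] != assignment.labels[v]
        assert assignment.n_reactions <= _chromatic_number(6, edges) + 1


def test_partition_invariant_to_nonconflicting_order():
    labels1 = partition_reactions(_fake_pairs(4), conflict=lambda a, b: False).labels
    labels2 = partition_reactions(
        list(reversed(_fake_pairs(4))), conflict=lambda a, b: False
    ).labels
    assert labels1 == labels2
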