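"""Nei-Gojobori counting, Jukes-Cantor correction, selection and dating.

The counting routines are checked against an independent oracle written
here from first principles (recursive pathway enumeration over codon
intermediates) and, more loosely, against Biopython's NG86
implementation, which handles stop-adjacent site renormalization
differently.
"""

import itertools
import math

import pytest

from genefam.errors import SequenceError, ValidationError
from genefam.molevol import (
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    back_translate,
    classify_selection,
    compute_kaks,
    count_differences,
    count_sites,
    divergence_time,
    jukes_cantor,
    kaks_for_pair,
)

# ---------------------------------------------------------------------------
# Independent oracles (deliberately different structure from the package code)


def oracle_sites(codon):
    syn = 0.0
    for pos, ref in enumerate(codon):
        alts = [codon[:pos] + b + codon[pos + 1 :] for b in "ACGT" if b != ref]
        legal = [a for a in alts if a not in STOP_CODONS]
        if legal:
            syn += sum(GENETIC_CODE[a] == GENETIC_CODE[codon] for a in legal) / len(legal)
    return syn, 3.0 - syn


def oracle_differences(a, b):
    """Recursive DFS over all orders of fixing mismatched positions."""
    paths = []

    def recurse(cur, syn, nonsyn):
        mism = [i for i in range(3) if cur[i] != b[i]]
        if not mism:
            paths.append((syn, nonsyn))
            return
        for i in mism:
            nxt = cur[:i] + b[i] + cur[i + 1 :]
            if nxt in STOP_CODONS:
                continue
            step_syn = GENETIC_CODE[nxt] == GENETIC_CODE[cur]
            recurse(nxt, syn + step_syn, nonsyn + (not step_syn))

    recurse(a, 0, 0)
    if not paths:
        return None
    # each complete DFS path is one legal permutation of the mismatches
    n = len(paths)
    return sum(p[0] for p in paths) / n, sum(p[1] for p in paths) / n


# ---------------------------------------------------------------------------


class TestCountSites:
    @pytest.mark.parametrize(
        "codon,s,n",
        [("TTT", 1 / 3, 8 / 3), ("ATG", 0.0, 3.0), ("CTT", 1.0, 2.0)],
    )
    def test_worked_examples(self, codon, s, n):
        S, N = count_sites(codon)
        assert S == pytest.approx(s)
        assert N == pytest.approx(n)

    def test_conservation_and_oracle_over_all_sense_codons(self):
        for codon in SENSE_CODONS:
            S, N = count_sites(codon)
            assert S + N == pytest.approx(3.0)
            assert (S, N) == pytest.approx(oracle_sites(codon))

    @pytest.mark.parametrize("bad", ["TAA", "TAG", "TGA", "NNN", "AC"])
    def test_stop_or_ambiguous_input_rejected(self, bad):
        with pytest.raises(SequenceError):
            count_sites(bad)


class TestCountDifferences:
    @pytest.mark.parametrize(
        "a,b,sd,nd",
        [
            ("TTT", "TTT", 0.0, 0.0),
            ("TTT", "TTC", 1.0, 0.0),
            ("TTT", "GTA", 0.5, 1.5),
        ],
    )
    def test_worked_examples(self, a, b, sd, nd):
        assert count_differences(a, b) == pytest.approx((sd, nd))

    def test_oracle_equivalence_over_all_sense_codon_pairs(self):
        for a, b in itertools.product(SENSE_CODONS, repeat=2):
            got = count_differences(a, b)
            expected = oracle_differences(a, b)
            assert expected is not None  # no fully blocked pair in the standard code
            k = sum(x != y for x, y in zip(a, b))
            assert got == pytest.approx(expected)
            assert got[0] + got[1] == pytest.approx(k)

    def test_symmetric_in_codon_order(self):
        for a, b in [("TTT", "GTA"), ("ATG", "CGC"), ("AAA", "GGG")]:
            assert count_differences(a, b) == pytest.approx(count_differences(b, a))


class TestJukesCantor:
    def test_small_p_limit(self):
        for p in (1e-4, 1e-3, 5e-3, 9e-3):
            assert jukes_cantor(p) == pytest.approx(p, rel=0.01)

    def test_saturation_rejected(self):
        with pytest.raises(ValidationError):
            jukes_cantor(0.75)

    def test_monotone(self):
        ds = [jukes_cantor(p) for p in (0.0, 0.1, 0.3, 0.5, 0.7)]
        assert ds == sorted(ds) and ds[0] == 0.0


class TestBackTranslate:
    def test_direct_mapping(self):
        aln = back_translate("MK", "MK", "ATGAAA", "ATGAAG")
        assert aln.columns == [("ATG", "ATG"), ("AAA", "AAG")]

    def test_gap_column_dropped_from_counts(self):
        aln = back_translate("M-K", "MQK", "ATGAAA", "ATGCAAAAA")
        assert len(aln.columns) == 3
        assert len(aln.comparable_columns) == 2

    def test_translation_mismatch_names_position(self):
        with pytest.raises(SequenceError, match="residue 2"):
            back_translate("MK", "MK", "ATGCCC", "ATGAAA")

    def test_terminal_stop_tolerated(self):
        aln = back_translate("MK", "MK", "ATGAAATAA", "ATGAAG")
        assert len(aln.columns) == 2


class TestComputeKaKs:
    def test_identical_sequences_give_zero_rates(self):
        aln = back_translate("L" * 10, "L" * 10, "CTT" * 10, "CTT" * 10)
        res = compute_kaks(aln)
        assert res.Ks == res.Ka == 0.0
        assert res.ratio is None and res.selection == "undefined"

    def test_single_synonymous_change_worked_example(self):
        aln = back_translate("L" * 10, "L" * 10, "CTT" * 10, "CTT" * 9 + "CTC")
        res = compute_kaks(aln)
        assert (res.S, res.N, res.Sd, res.Nd) == (10.0, 20.0, 1.0, 0.0)
        assert res.pS == pytest.approx(0.1)
        assert res.Ks == pytest.approx(0.10733, abs=1e-5)
        assert res.Ka == 0.0

    def test_symmetry_in_sequence_order(self, planted_family):
        a, b = planted_family["tanA1"], planted_family["tanA2"]
        r1 = kaks_for_pair(a, b)
        r2 = kaks_for_pair(b, a)
        assert r1.Ks == pytest.approx(r2.Ks, abs=1e-12)
        assert r1.Ka == pytest.approx(r2.Ka, abs=1e-12)

    def test_agrees_loosely_with_biopython_ng86(self, planted_family):
        # Biopython's NG86 differs in stop-adjacent site renormalization,
        # so agreement is approximate, not exact
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        a, b = planted_family["segB1"], planted_family["segB2"]
        dn, ds = cal_dn_ds(CodonSeq(a.cds), CodonSeq(b.cds), method="NG86")
        res = kaks_for_pair(a, b)
        assert res.Ka == pytest.approx(dn, rel=0.1)
        assert res.Ks == pytest.approx(ds, rel=0.1)

    def test_no_comparable_columns_rejected(self):
        aln = back_translate("M-", "-K", "ATG", "AAA")
        with pytest.raises(ValidationError):
            compute_kaks(aln)


class TestSelectionAndDating:
    @pytest.mark.parametrize(
        "ratio,mode",
        [(0.593, "purifying"), (1.483, "positive"), (1.0, "neutral"), (None, "undefined")],
    )
    def test_published_and_boundary_modes(self, ratio, mode):
        assert classify_selection(ratio) == mode

    @pytest.mark.parametrize("ks,mya", [(0.566, 18.87), (0.398, 13.27), (0.0, 0.0)])
    def test_published_divergence_times(self, ks, mya):
        assert divergence_time(ks) == pytest.approx(mya, abs=0.005)

    def test_linear_in_ks_and_inverse_in_rate(self):
        assert divergence_time(0.2) == pytest.approx(2 * divergence_time(0.1))
        assert divergence_time(0.2, r=3.0e-8) == pytest.approx(
            divergence_time(0.2) / 2
        )

    def test_negative_ks_rejected(self):
        with pytest.raises(ValidationError):
            divergence_time(-0.1)
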