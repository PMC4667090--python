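import itertools
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tetrasnp import pipeline, simpanel
from tetrasnp.ampliconobs import AmpliconObservation, observe_amplicon
from tetrasnp.classify import (
    AlignParams,
    align_global,
    classify_sites,
    collapse_variant_class,
    detect_psv,
    infer_copy_composition,
)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# strand-collapsed classes


class TestCollapseVariantClass:
    @pytest.mark.parametrize(
        "pair,expected",
        [
            (("G", "A"), "C/T(G/A)"),
            (("C", "T"), "C/T(G/A)"),
            (("G", "T"), "A/C(T/G)"),
            (("A", "C"), "A/C(T/G)"),
            (("T", "A"), "A/T(T/A)"),
            (("C", "G"), "C/G(G/C)"),
        ],
    )
    def test_examples(self, pair, expected):
        assert collapse_variant_class(*pair) == expected

    def test_identical_rejected(self):
        with pytest.raises(ValueError):
            collapse_variant_class("A", "A")

    def test_strand_symmetry_all_12_ordered_pairs(self):
        for x, y in itertools.permutations("ACGT", 2):
            assert collapse_variant_class(x, y) == collapse_variant_class(
                COMPLEMENT[x], COMPLEMENT[y]
            )

    def test_four_of_twelve_collapse_to_ct_ga(self):
        labels = [
            collapse_variant_class(x, y)
            for x, y in itertools.permutations("ACGT", 2)
        ]
        assert labels.count("C/T(G/A)") == 4


# ---------------------------------------------------------------------------
# global alignment


def oracle_score(a: str, b: str, params: AlignParams) -> float:
    """Independent top-down memoized scoring of the same alignment problem.

    States: 0 = no open gap, 1 = gap in b open, 2 = gap in a open. A gap of
    length k costs gap_open + k * gap_extend.
    """
    from tetrasnp.ampliconobs import iupac_decompose

    neg = float("-inf")

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = [neg]
        if i < len(a) and j < len(b):
            s = (
                params.match
                if iupac_decompose(a[i]) & iupac_decompose(b[j])
                else params.mismatch
            )
            options.append(s + best(i + 1, j + 1, 0))
        if i < len(a):  # consume a[i] against a gap in b
            cost = params.gap_extend + (params.gap_open if state != 1 else 0.0)
            options.append(cost + best(i + 1, j, 1))
        if j < len(b):
            cost = params.gap_extend + (params.gap_open if state != 2 else 0.0)
            options.append(cost + best(i, j + 1, 2))
        return max(options)

    return best(0, 0, 0)


class TestAlignGlobal:
    def test_identical(self):
        aln = align_global("ACGT", "ACGT")
        assert aln.identity == 1.0
        assert aln.score == 4 * AlignParams().match
        assert aln.aligned_query == "ACGT"

    def test_ambiguity_aware_match(self):
        # Y decomposes to {C,T}: intersects C and T, not G
        assert align_global("ACTT", "ACYT").identity == 1.0
        assert align_global("ACCT", "ACYT").identity == 1.0
        assert align_global("ACGT", "ACYT").identity == 0.75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_global("", "ACGT")

    def test_ungapping_reproduces_inputs(self):
        aln = align_global("ACGTTT", "AGTT")
        assert aln.aligned_query.replace("-", "") == "ACGTTT"
        assert aln.aligned_ref.replace("-", "") == "AGTT"

    def test_gap_scoring(self):
        params = AlignParams(match=2.0, mismatch=-1.0, gap_open=-4.0, gap_extend=-1.0)
        aln = align_global("AACCGG", "AAGG", params)
        # 4 matches + one gap of length 2
        assert aln.score == 4 * 2.0 + (-4.0 - 2.0)

    def test_matches_independent_oracle_on_random_short_sequences(self):
        rng = np.random.default_rng(0)
        params = AlignParams()
        for _ in range(50):
            n, m = rng.integers(1, 13, size=2)
            a = "".join(rng.choice(list("ACGT"), size=n))
            b = "".join(rng.choice(list("ACGT"), size=m))
            assert align_global(a, b, params).score == oracle_score(a, b, params)


# ---------------------------------------------------------------------------
# copy composition

A_SEQ = "ACGTACGTACGTACGTACGT"
B_SEQ = "ACGTACGTTCGTACGAACGT"  # differs at 8 and 15


def _obs(seq, genotype="g", locus="L1"):
    return AmpliconObservation(locus, genotype, seq)


class TestInferCopyComposition:
    def test_both_retained(self):
        tetra = observe_amplicon([A_SEQ, B_SEQ], "L1", "tetra")
        comp = infer_copy_composition(tetra, _obs(A_SEQ), _obs(B_SEQ))
        assert comp.hypothesis == "AB"
        assert comp.explained
        assert comp.mismatch_count == 0

    def test_b_copy_eliminated(self):
        comp = infer_copy_composition(
            _obs(A_SEQ, "tetra"), _obs(A_SEQ), _obs(B_SEQ)
        )
        assert comp.hypothesis == "A_only"
        assert comp.explained

    def test_a_paralogs(self):
        # heterozygous A progenitor, tetraploid shows exactly its superposition,
        # inconsistent with any B-containing copy set
        a1 = A_SEQ
        a2 = A_SEQ[:4] + "T" + A_SEQ[5:12] + "C" + A_SEQ[13:]
        prog_a = observe_amplicon([a1, a2], "L1", "progA")
        tetra = observe_amplicon([a1, a2], "L1", "tetra")
        comp = infer_copy_composition(tetra, prog_a, _obs(B_SEQ))
        assert comp.hypothesis == "A_paralogs"
        assert comp.explained

    def test_ab_with_paralogs(self):
        a1 = A_SEQ
        a2 = A_SEQ[:4] + "T" + A_SEQ[5:]
        prog_a = observe_amplicon([a1, a2], "L1", "progA")
        tetra = observe_amplicon([a1, a2, B_SEQ], "L1", "tetra")
        comp = infer_copy_composition(tetra, prog_a, _obs(B_SEQ))
        assert comp.hypothesis == "AB_paralogs"
        assert comp.copy_labels == ("A1", "A2", "B1")
        assert comp.explained

    def test_identical_progenitors_prefer_ab(self):
        comp = infer_copy_composition(
            _obs(A_SEQ, "tetra"), _obs(A_SEQ), _obs(A_SEQ)
        )
        assert comp.hypothesis == "AB"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            infer_copy_composition(
                _obs("ACGT"), _obs("ACGT"), _obs("ACGTA")
            )

    def test_unexplained_mismatch_count(self):
        tetra = _obs("TTTTTTTTTTTTTTTTTTTT", "tetra")
        comp = infer_copy_composition(tetra, _obs(A_SEQ), _obs(B_SEQ))
        assert not comp.explained
        assert comp.mismatch_count > 0


class TestDetectPsv:
    def test_homozygous_none(self):
        assert detect_psv(_obs(A_SEQ)) == []

    def test_single_r(self):
        seq = A_SEQ[:10] + "R" + A_SEQ[11:]
        sites = detect_psv(_obs(seq), genome="A")
        assert len(sites) == 1
        assert sites[0].position == 11  # 1-based
        assert sites[0].alleles == ("A", "G")
        assert sites[0].subgenome == "within-A"

    def test_complex_position_excluded(self, caplog):
        seq = A_SEQ[:10] + "V" + A_SEQ[11:]  # {A,C,G}
        with caplog.at_level("WARNING"):
            sites = detect_psv(_obs(seq))
        assert sites == []
        assert "complex" in caplog.text

    def test_matches_generator_truth(self, clean_panel):
        for locus in clean_panel.loci:
            if len(locus.a_copies) == 2:
                obs = observe_amplicon(locus.a_copies, locus.locus_id, "progA")
                found = {s.position - 1 for s in detect_psv(obs, "A")}
                truth = {
                    t.position
                    for t in locus.truth_sites
                    if t.subgenome == "within-A"
                }
                assert found == truth


# ---------------------------------------------------------------------------
# site classification


def _make_panel(a_seq, b_seq, variety_copies):
    prog_a = _obs(a_seq, "progA")
    prog_b = _obs(b_seq, "progB")
    panel = {
        name: observe_amplicon(copies, "L1", name)
        for name, copies in variety_copies.items()
    }
    consensus = pipeline.majority_observation(panel)
    comp = infer_copy_composition(consensus, prog_a, prog_b)
    return panel, prog_a, prog_b, comp


class TestClassifySites:
    def test_fixed_ab_difference_is_hsv(self):
        varieties = {f"V{i}": [A_SEQ, B_SEQ] for i in range(12)}
        panel, pa, pb, comp = _make_panel(A_SEQ, B_SEQ, varieties)
        sites = classify_sites(panel, pa, pb, comp)
        assert [s.category for s in sites] == ["HSV", "HSV"]
        assert [s.position for s in sites] == [9, 16]
        assert all(s.subgenome == "between" for s in sites)

    def test_segregating_column_is_snp(self):
        a_minor = A_SEQ[:2] + "T" + A_SEQ[3:]  # G->T at offset 2
        varieties = {
            f"V{i}": [a_minor if i < 3 else A_SEQ, B_SEQ] for i in range(12)
        }
        panel, pa, pb, comp = _make_panel(A_SEQ, B_SEQ, varieties)
        snps = [s for s in classify_sites(panel, pa, pb, comp) if s.category == "SNP"]
        assert len(snps) == 1
        snp = snps[0]
        assert snp.position == 3
        assert snp.alleles == ("G", "T")
        assert snp.n_varieties_minor == 3
        assert not snp.hsv_coincident

    def test_snp_at_hsv_column_flagged_coincident(self):
        # B fixed T, A segregates C/T at offset 8 (the CTxCC pattern)
        a_minor = A_SEQ[:8] + "C" + A_SEQ[9:]  # A allele C instead of A
        varieties = {
            f"V{i}": [a_minor if i < 4 else A_SEQ, B_SEQ] for i in range(12)
        }
        panel, pa, pb, comp = _make_panel(A_SEQ, B_SEQ, varieties)
        snps = [
            s
            for s in classify_sites(panel, pa, pb, comp)
            if s.category == "SNP" and s.position == 9
        ]
        assert len(snps) == 1
        assert snps[0].hsv_coincident

    def test_refuses_unexplained_composition(self):
        varieties = {f"V{i}": [A_SEQ, B_SEQ] for i in range(4)}
        panel, pa, pb, _ = _make_panel(A_SEQ, B_SEQ, varieties)
        bad = infer_copy_composition(
            _obs("T" * len(A_SEQ), "tetra"), pa, pb
        )
        with pytest.raises(ValueError, match="unexplained"):
            classify_sites(panel, pa, pb, bad)

    def test_needs_two_varieties(self):
        varieties = {"V0": [A_SEQ, B_SEQ]}
        panel, pa, pb, comp = _make_panel(A_SEQ, B_SEQ, varieties)
        with pytest.raises(ValueError, match="two varieties"):
            classify_sites(panel, pa, pb, comp)


class TestClassifierAgainstTruth:
    def _recovery(self, panel):
        _, sites, table = pipeline.classify_panel(panel)
        assert table["explained"].all()
        return pipeline.score_recovery(panel, sites)

    def test_full_recovery_clean_regime(self, clean_panel):
        recovery = self._recovery(clean_panel)
        assert recovery["recovery_fraction"] == 1.0
        assert recovery["n_false_categories"] == 0

    def test_recovery_with_elimination(self, small_panel):
        recovery = self._recovery(small_panel)
        assert recovery["recovery_fraction"] >= 0.95

    def test_partition_every_variable_column_once(self, clean_panel):
        _, sites, _ = pipeline.classify_panel(clean_panel)
        seen = [(s.locus_id, s.position) for s in sites]
        assert len(seen) == len(set(seen))
        n_truth = sum(
            len(panel_locus.truth_sites) for panel_locus in clean_panel.loci
        )
        resolved = [s for s in sites if s.category != "unresolved"]
        assert len(resolved) == n_truth

    def test_no_snp_calls_when_snp_rate_zero(self):
        cfg = simpanel.SimConfig(
            n_loci=15,
            locus_length_bp=300,
            n_varieties=8,
            snp_rate=0.0,
            psv_dup_prob=0.3,
            elimination_prob_single=0.0,
            elimination_prob_multi=0.0,
            sequencing_fail_prob=0.0,
            seed=17,
        )
        panel = simpanel.simulate_tetraploid_panel(
            simpanel.simulate_progenitors(cfg), cfg
        )
        _, sites, _ = pipeline.classify_panel(panel)
        assert all(s.category in {"HSV", "PSV"} for s in sites)


@given(st.text(alphabet="ACGT", min_size=4, max_size=12))
def test_composition_self_consistency(seq):
    # a tetraploid identical to both (identical) progenitors is explained
    comp = infer_copy_composition(_obs(seq, "t"), _obs(seq), _obs(seq))
    assert comp.explained
    assert comp.hypothesis == "AB"
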