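"""CDR3 feature derivation and junction decomposition.

The decomposition tests compare the implementation against a brute-force
oracle that enumerates every (V prefix, D substring placement, J suffix)
decomposition by direct string comparison.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdr3delta.annotation import (
    HYDROPHOBIC_AA5,
    AnnotationError,
    classify_j_region_by_suffix,
    compute_cdr3_length,
    decompose_junction,
    detect_inv_t,
    extract_aa5,
)
from cdr3delta.simulate import PUBLIC_CLONOTYPES

from conftest import make_clonotype, make_sample

#: Published CDR3delta lengths of the highly common public clonotypes.
PUBLIC_CLONOTYPE_LENGTHS = {
    "CACDTLGDTDKLIF": 12,
    "CACDTLLGDTDKLIF": 13,
    "CACDVLGDTDKLIF": 12,
    "CACDTLGVYTDKLIF": 13,
    "CACDTVGDTDKLIF": 12,
    "CACDTVGEYTDKLIF": 13,
    "CACDTVGGYTDKLIF": 13,
    "CACDILGDTDKLIF": 12,
    "CACDPLGDTDKLIF": 12,
    "CACDTAGGSSWDTRQMFF": 16,
    "CACDTVGGTDKLIF": 12,
    "CACDTVGTYTDKLIF": 13,
    "CACDTWGTDKLIF": 11,
    "CACDTWGYTDKLIF": 12,
}


def oracle_best_score(junction_nt, reference, min_d_match=3):
    """Exhaustive maximum-germline-attribution score by direct enumeration."""
    L = len(junction_nt)
    vreg = reference.v_junction_region()
    v_lens = [v for v in range(min(len(vreg), L) + 1) if junction_nt[:v] == vreg[:v]]
    j_lens = {0}
    for region in reference.j_regions():
        jreg = reference.j_junction_region(region)
        for j in range(1, min(len(jreg), L) + 1):
            if junction_nt[L - j :] == jreg[len(jreg) - j :]:
                j_lens.add(j)
    d_seqs = [d.nt_sequence for d in reference.d_segments()]
    best = 0
    for v in v_lens:
        for j in j_lens:
            if v + j > L:
                continue
            middle = junction_nt[v : L - j]
            best_d = 0
            for d_nt in d_seqs:
                for s in range(len(middle)):
                    for e in range(s + min_d_match, len(middle) + 1):
                        if e - s <= len(d_nt) and middle[s:e] in d_nt:
                            best_d = max(best_d, e - s)
            best = max(best, v + j + best_d)
    return best


@pytest.mark.parametrize("junction_aa, expected", sorted(PUBLIC_CLONOTYPE_LENGTHS.items()))
def test_cdr3_length_excludes_the_two_anchors(junction_aa, expected):
    assert compute_cdr3_length(junction_aa) == expected


def test_cdr3_length_edge_cases():
    assert compute_cdr3_length("CAF") == 1
    with pytest.raises(AnnotationError):
        compute_cdr3_length("CA")
    with pytest.raises(AnnotationError):
        compute_cdr3_length("AACDTLGDTDKLIF")  # missing C anchor


@pytest.mark.parametrize(
    "junction_aa, aa5, hydrophobic",
    [
        ("CACDTLGDTDKLIF", "L", True),
        ("CACDTEGTPTLLIF", "E", False),
        ("CACDTAGGSSWDTRQMFF", "A", True),
    ],
)
def test_aa5_is_sixth_junction_residue(junction_aa, aa5, hydrophobic):
    assert extract_aa5(junction_aa) == (aa5, hydrophobic)


def test_aa5_undefined_for_short_junctions():
    assert extract_aa5("CACDKF") is None


@pytest.mark.parametrize(
    "codon6, expected",
    [("CTG", True), ("CTC", True), ("GCC", False), ("GGA", False), ("ACC", False)],
)
def test_invt_is_template_t_at_second_base_of_codon_six(codon6, expected):
    from Bio.Seq import Seq

    nt = "TGTGCCTGTGACACC" + codon6 + "GGGGATACCGATAAACTCATCTTT"
    aa = str(Seq(nt).translate())
    assert detect_inv_t(nt, aa) is expected


def test_invt_requires_consistent_frame():
    with pytest.raises(AnnotationError):
        detect_inv_t("TGTGCCTGTGACACCCTGGGGGATACCGATAAACTCATCTTT", "CACDTVGDTDKLIF")


def test_invt_implies_hydrophobic_aa5():
    # residues encodable with T at the codon's second position are a subset
    # of the hydrophobic set, so invT must imply hAA5 on any input
    from Bio.Seq import Seq

    rng = np.random.default_rng(7)
    for _ in range(300):
        codon6 = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
        nt = "TGTGCCTGTGACACC" + codon6 + "ACCGATAAACTCATCTTT"
        aa = str(Seq(nt).translate())
        if "*" in aa:
            continue
        if detect_inv_t(nt, aa):
            assert extract_aa5(aa)[1] is True


def test_public_clonotypes_uniformly_hydrophobic_at_aa5():
    for aa in PUBLIC_CLONOTYPES:
        assert extract_aa5(aa)[1] is True


def test_decomposition_of_pure_germline_concatenation(reference):
    jnt = (
        reference.v_junction_region()
        + reference["TRDD3*01"].nt_sequence
        + reference.j_junction_region("J1")
    )
    dec = decompose_junction(jnt, reference)
    assert dec.total_n == 0 and dec.germline_encoded
    assert dec.v_match_len == 15
    assert dec.d_segment == "TRDD3*01" and dec.d_match_len == 13
    assert dec.j_match_len == 20
    assert dec.score == len(jnt)


def test_decomposition_counts_inserted_block(reference):
    base_v = reference.v_junction_region()
    jnt = base_v + "GGC" + reference["TRDD3*01"].nt_sequence + reference.j_junction_region("J1")
    dec = decompose_junction(jnt, reference)
    assert (dec.n1_len, dec.n2_len) == (3, 0)
    assert dec.total_n == 3 and not dec.germline_encoded
    assert dec.score == oracle_best_score(jnt, reference)


def test_unmatchable_junction_is_all_n(reference):
    rng = np.random.default_rng(11)
    vreg = reference.v_junction_region()
    jregs = [reference.j_junction_region(r) for r in reference.j_regions()]
    d3mers = {
        d.nt_sequence[i : i + 3]
        for d in reference.d_segments()
        for i in range(len(d.nt_sequence) - 2)
    }
    while True:
        jnt = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
        if jnt[0] == vreg[0] or any(jnt[-1] == jr[-1] for jr in jregs):
            continue
        if any(jnt[i : i + 3] in d3mers for i in range(19)):
            continue
        break
    dec = decompose_junction(jnt, reference)
    assert dec.v_match_len == 0 and dec.j_match_len == 0 and dec.d_match_len == 0
    assert dec.total_n == 21 and dec.score == 0


def test_decomposition_score_matches_oracle_on_random_junctions(reference):
    rng = np.random.default_rng(23)
    vreg = reference.v_junction_region()
    d3 = reference["TRDD3*01"].nt_sequence
    j1 = reference.j_junction_region("J1")
    for trial in range(60):
        if trial % 2 == 0:
            jnt = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(6, 49))))
        else:  # germline-flavoured junctions exercise long matches and ties
            v = vreg[: rng.integers(0, 16)]
            mid = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(0, 7))))
            d = d3[rng.integers(0, 6) : rng.integers(7, 14)]
            j = j1[rng.integers(0, 21) :]
            jnt = (v + mid + d + j)[:48]
            if not jnt:
                continue
        dec = decompose_junction(jnt, reference)
        assert dec.score == oracle_best_score(jnt, reference), jnt


@settings(derandomize=True, max_examples=100)
@given(st.text(alphabet="ACGT", min_size=1, max_size=48))
def test_decomposition_blocks_always_sum_to_junction_length(reference, junction):
    dec = decompose_junction(junction, reference)
    total = dec.v_match_len + dec.n1_len + dec.d_match_len + dec.n2_len + dec.j_match_len
    assert total == len(junction)
    assert dec.score == len(junction) - dec.total_n
    assert min(dec.v_match_len, dec.n1_len, dec.d_match_len, dec.n2_len, dec.j_match_len) >= 0


def test_decomposition_is_deterministic(reference):
    jnt = reference.v_junction_region() + "GGCC" + reference.j_junction_region("J1")[4:]
    assert decompose_junction(jnt, reference) == decompose_junction(jnt, reference)


@pytest.mark.parametrize(
    "junction_aa, region",
    [("CACDTLGDTDKLIF", "J1"), ("CACDTAGGSSWDTRQMFF", "J3")],
)
def test_j_region_suffix_classification(junction_aa, region, reference):
    assert classify_j_region_by_suffix(junction_aa, reference) == region


def test_j_call_takes_precedence_over_suffix(reference):
    from cdr3delta.annotation import annotate_clonotypes

    # junction whose suffix says J1, but the upstream caller said TRDJ3
    c = make_clonotype(
        "TGTGCCTGTGACACCCTGGGGGATACCGATAAACTCATCTTT",
        "CACDTLGDTDKLIF",
        5,
        j_call="TRDJ3*01",
    )
    ann = annotate_clonotypes([make_sample([c])], reference)
    assert ann.loc[0, "j_region"] == "J3"


def test_no_suffix_overlap_is_unclassified(reference):
    assert classify_j_region_by_suffix("CAAAAAAAAW", reference) is None


def test_invt_germline_origin_variant(reference):
    from Bio.Seq import Seq

    # junction whose codon-6 T is D3-encoded (CTG from the TRDD3 frame)
    jnt = reference.v_junction_region() + "CTGGGGGAT" + reference.j_junction_region("J1")[2:]
    aa = str(Seq(jnt).translate())
    dec = decompose_junction(jnt, reference)
    assert detect_inv_t(jnt, aa) is True
    assert detect_inv_t(jnt, aa, dec, require_germline_origin=True) is True
    # invT residue encoded by inserted nucleotides that no D segment can
    # absorb: plain invT yes, germline-origin variant no
    jnt2 = "TGTGCCTGTGACACC" + "GTA" + "ACCGATAAACTCATCTTT"  # Val via GTA insert
    aa2 = str(Seq(jnt2).translate())
    dec2 = decompose_junction(jnt2, reference)
    assert detect_inv_t(jnt2, aa2) is True
    d_cov = range(dec2.d_start_in_junction, dec2.d_start_in_junction + dec2.d_match_len)
    assert 16 not in d_cov
    assert detect_inv_t(jnt2, aa2, dec2, require_germline_origin=True) is False
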