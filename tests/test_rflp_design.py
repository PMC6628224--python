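import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from passalus.alignment_io import Alignment
from passalus.rflp_design import (
    IUPAC_SETS,
    Enzyme,
    GelParams,
    NoAmplificationError,
    NoDiagnosticSiteError,
    PrimerPair,
    clade_consensus,
    design_assays,
    digest,
    expected_fragment_table,
    extract_amplicon,
    fixed_differences,
    packaged_enzymes,
    reverse_complement,
    scan_recognition_sites,
)
from passalus.synthetic_data import REFERENCE_PRIMERS

ENZ = {e.name: e for e in packaged_enzymes()}
TAQI, BSAI, DDEI = ENZ["TaqI"], ENZ["BsaI"], ENZ["DdeI"]


def _aln(*recs):
    return Alignment.from_records(recs)


def _brute_force_cuts(seq, enzyme):
    """Independent oracle: expand every window of the sequence and of its
    reverse complement into concrete strings and compare with the expanded
    recognition set (conservative: all window expansions must match)."""
    def window_matches(window, pattern):
        expansions = itertools.product(*(sorted(IUPAC_SETS[c]) for c in window))
        return all(
            all(b in IUPAC_SETS[p] for b, p in zip(exp, pattern)) for exp in expansions
        )

    L, k = len(seq), len(enzyme.recognition)
    cuts = set()
    for s in range(L - k + 1):
        if "-" not in seq[s : s + k] and window_matches(seq[s : s + k], enzyme.recognition):
            cut = s + enzyme.cut_offset
            if 0 < cut < L:
                cuts.add(cut)
    if not enzyme.palindromic:
        rc = reverse_complement(seq)
        for s in range(L - k + 1):
            if "-" not in rc[s : s + k] and window_matches(rc[s : s + k], enzyme.recognition):
                cut = L - (s + enzyme.cut_offset)
                if 0 < cut < L:
                    cuts.add(cut)
    return sorted(cuts)


class TestCladeConsensus:
    def test_unanimous_and_split_columns(self):
        aln = _aln(("a1", "CC"), ("a2", "CT"), ("b1", "GG"), ("b2", "GG"))
        cons = clade_consensus(aln, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert cons["A"] == "CY"  # {C}, {C,T}
        assert cons["B"] == "GG"

    def test_all_undetermined_column_is_n(self):
        aln = _aln(("a1", "NC"), ("a2", "-C"), ("b1", "AC"))
        cons = clade_consensus(aln, {"a1": "A", "a2": "A", "b1": "B"})
        assert cons["A"] == "NC"

    def test_empty_clade_errors(self):
        with pytest.raises(ValueError):
            clade_consensus(_aln(("a1", "AC")), {"a1": "A", "ghost": "B"})


class TestFixedDifferences:
    def test_disjoint_singletons_detected(self):
        aln = _aln(("a1", "ACA"), ("a2", "ACA"), ("b1", "ATA"), ("b2", "ATA"))
        sites = fixed_differences(aln, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert [s.position for s in sites] == [2]
        assert sites[0].state_by_clade == {"A": "C", "B": "T"}

    def test_polymorphic_clade_excludes_site(self):
        aln = _aln(("a1", "AC"), ("a2", "AT"), ("b1", "AG"), ("b2", "AG"))
        assert fixed_differences(aln, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}) == []

    def test_undetermined_member_does_not_veto(self):
        aln = _aln(("a1", "AC"), ("a2", "AN"), ("b1", "AT"), ("b2", "AT"))
        sites = fixed_differences(aln, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert [s.position for s in sites] == [2]


class TestExtractAmplicon:
    F = REFERENCE_PRIMERS.forward  # 23 nt
    R = REFERENCE_PRIMERS.reverse  # 25 nt

    def test_published_frame_yields_244_bp(self):
        rng = np.random.default_rng(0)
        insert = "".join(rng.choice(list("ACGT"), 196))
        seq = "GG" + self.F + insert + reverse_complement(self.R) + "TTT"
        amp = extract_amplicon(seq, REFERENCE_PRIMERS)
        assert len(amp) == 23 + 196 + 25 == 244
        assert amp.startswith(self.F) and amp.endswith(reverse_complement(self.R))

    def test_absent_primer_errors(self):
        with pytest.raises(NoAmplificationError):
            extract_amplicon("ACGT" * 30, REFERENCE_PRIMERS)

    def test_degenerate_primer_binds_both_variants(self):
        # R in the forward primer binds A and G templates at the same span
        primers = PrimerPair(forward="AAAAACCCCCGGGGRTTTTT", reverse="AAAAACCCCCGGGGGTTTTT")
        rc_rev = reverse_complement(primers.reverse)
        for mid in "AG":
            template = "AAAAACCCCCGGGG" + mid + "TTTTT" + "CACACACA" + rc_rev
            amp = extract_amplicon(template, primers)
            assert len(amp) == 20 + 8 + 20

    def test_mismatch_budget(self):
        rng = np.random.default_rng(1)
        insert = "".join(rng.choice(list("ACGT"), 30))
        mutated_f = "G" + self.F[1:]
        seq = mutated_f + insert + reverse_complement(self.R)
        with pytest.raises(NoAmplificationError):
            extract_amplicon(seq, REFERENCE_PRIMERS)
        lax = PrimerPair(self.F, self.R, max_mismatch=1)
        assert len(extract_amplicon(seq, lax)) == 23 + 30 + 25


class TestScanRecognitionSites:
    def test_taqi_hand_placed(self):
        assert scan_recognition_sites("AATCGAAA", TAQI) == [3]

    def test_ddei_degenerate_n_matches_any_base(self):
        for mid in "ACGT":
            assert scan_recognition_sites(f"AACT{mid}AGAA", DDEI) == [3]

    def test_bsai_site_on_bottom_strand_still_cuts(self):
        # top strand carries only the reverse-complement of GGTCTCN
        seq = "AAAA" + reverse_complement("GGTCTCA") + "AAAA"
        assert scan_recognition_sites(seq, BSAI) == [4]

    def test_type_iis_cut_outside_sequence_discarded(self):
        # recognition present but the downstream cut would fall at the boundary
        assert scan_recognition_sites("AAGGTCTCA", BSAI) == []

    def test_ambiguous_template_base_conservative(self):
        # Y in the template could be C or T; TaqI requires C -> no cut called
        assert scan_recognition_sites("AATYGAAA", TAQI) == []
        assert scan_recognition_sites("AATNGAAA", TAQI) == []

    @pytest.mark.parametrize("enzyme", [TAQI, BSAI, DDEI], ids=lambda e: e.name)
    def test_matches_brute_force_oracle(self, enzyme):
        rng = np.random.default_rng(17)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGTN"), rng.integers(20, 300)))
            assert scan_recognition_sites(seq, enzyme) == _brute_force_cuts(seq, enzyme)


class TestDigest:
    def test_no_site_single_fragment(self):
        fp = digest("A" * 50, [TAQI])
        assert fp.fragments == (50,) and fp.source_cuts == ()

    def test_fragments_are_successive_cut_differences(self):
        seq = "A" * 10 + "TCGA" + "C" * 10 + "TCGA" + "G" * 10
        fp = digest(seq, [TAQI])
        assert fp.source_cuts == (11, 25)
        assert fp.fragments == (11, 14, len(seq) - 25)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=400))
    def test_fragment_sum_conservation(self, seq):
        for enzymes in ([TAQI], [BSAI, DDEI], [TAQI, BSAI, DDEI]):
            fp = digest(seq, enzymes)
            assert sum(fp.fragments) == len(seq)

    def test_adding_enzyme_never_decreases_fragment_count(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 300))
            single = len(digest(seq, [TAQI]).fragments)
            double = len(digest(seq, [TAQI, DDEI]).fragments)
            assert double >= single


class TestDesignAssays:
    def _planted(self):
        # one fixed difference creates a TaqI site in clade B only
        core = "AAATTTGGGCCCAAATTTGGGCCC"
        a_seq = "CCCCCGGGGGAAAAACCCCC" + core + "TGGA" + core + "GGGGGAAAAACCCCCGGGGG"
        b_seq = a_seq.replace("TGGA", "TCGA")
        primers = PrimerPair(forward=a_seq[:20], reverse=reverse_complement(a_seq[-20:]))
        aln = _aln(("a1", a_seq), ("a2", a_seq), ("b1", b_seq), ("b2", b_seq))
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        return aln, labels, primers

    def test_single_enzyme_diagnostic_found_and_ranked_first(self):
        aln, labels, primers = self._planted()
        designs = design_assays(aln, labels, [TAQI, BSAI, DDEI], primers)
        assert designs and designs[0].enzymes == (TAQI,)
        assert designs[0].diagnostic

    def test_enzyme_cutting_all_haplotypes_identically_rejected(self):
        aln, labels, primers = self._planted()
        # DdeI does not distinguish the planted haplotypes
        designs = design_assays(aln, labels, [DDEI], primers)
        assert designs == []

    def test_no_fixed_difference_errors(self):
        seq = "CCCCCGGGGGAAAAACCCCC" + "ATATATAT" + "GGGGGAAAAACCCCCGGGGG"
        primers = PrimerPair(forward=seq[:20], reverse=reverse_complement(seq[-20:]))
        aln = _aln(("a1", seq), ("b1", seq))
        with pytest.raises(NoDiagnosticSiteError):
            design_assays(aln, {"a1": "A", "b1": "B"}, [TAQI], primers)

    def test_gel_filtering_hides_tiny_bands(self):
        aln, labels, primers = self._planted()
        strictest = GelParams(min_visible_bp=200, min_separation_pct=5)
        designs = design_assays(aln, labels, [TAQI], primers, gel=strictest)
        assert designs == []  # all diagnostic bands fall below visibility


class TestFragmentTable:
    def test_cells_render_ascending_and_conserve_length(self, standin):
        from passalus.synthetic_data import REFERENCE_PRIMERS

        aln, labels = standin.alignment, standin.truth_labels
        designs = design_assays(aln, labels, packaged_enzymes(), REFERENCE_PRIMERS)
        table = expected_fragment_table(designs)
        assert list(table.index) == ["Clade A", "Clade B"]
        for col in table.columns:
            for cell in table[col]:
                sizes = [int(x) for x in cell.split("/")]
                assert sizes == sorted(sizes)
                assert sum(sizes) == 244
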