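"""Peptide database construction: translation, digestion, pI, fractionation,
canonical subtraction, novelty classification, and the end-to-end build."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gscproteo.io import SequenceRecord
from gscproteo.proteogenomics import (
    PKA_BJELLQVIST,
    PeptideRecord,
    build_database,
    classify_novel,
    compute_pi,
    digest,
    filter_transcripts,
    flag_single_mismatch,
    fractionate,
    length_filter,
    subtract_canonical,
    translate_orfs,
)
from gscproteo.simulate import generate_toy_transcriptome

AA = "ACDEFGHIKLMNPQRSTVWY"


def pi_gridscan_oracle(peptide, step=1e-5):
    """Independent fine-grid sign-change scan of the net-charge curve."""
    counts = {"n_term": 1, "c_term": 1}
    for aa in peptide:
        if aa in PKA_BJELLQVIST:
            counts[aa] = counts.get(aa, 0) + 1
    grid = np.arange(0.0, 14.0 + step, step)
    charge = np.zeros_like(grid)
    for g in ("n_term", "H", "K", "R"):
        charge += counts.get(g, 0) / (1 + 10 ** (grid - PKA_BJELLQVIST[g]))
    for g in ("c_term", "D", "E", "C", "Y"):
        charge -= counts.get(g, 0) / (1 + 10 ** (PKA_BJELLQVIST[g] - grid))
    flip = np.nonzero(np.diff(np.sign(charge)) < 0)[0][0]
    return (grid[flip] + grid[flip + 1]) / 2


class TestTranslation:
    def test_simple_orf(self):
        orfs = translate_orfs(SequenceRecord("t", "ATGAAATAA", "dna"), min_aa=1)
        assert [o.protein for o in orfs] == ["MK"]
        assert not orfs[0].partial

    def test_short_orf_dropped_at_min_aa(self):
        assert translate_orfs(SequenceRecord("t", "ATGTGA", "dna"), min_aa=8) == []

    def test_no_start_codon_gives_empty_list(self):
        assert translate_orfs(SequenceRecord("t", "CCCCCCGGG", "dna")) == []

    def test_missing_stop_flagged_partial(self):
        orfs = translate_orfs(
            SequenceRecord("t", "ATG" + "GCT" * 10, "dna"), min_aa=5
        )
        assert orfs[0].partial
        assert orfs[0].protein == "M" + "A" * 10

    def test_non_dna_characters_rejected(self):
        with pytest.raises(ValueError):
            translate_orfs(SequenceRecord("t", "ATGJJJ", "dna"))


class TestDigest:
    def test_kr_rule_with_proline_suppression(self):
        assert digest("MKRPGLKAK") == ["MK", "RPGLK", "AK"]

    def test_no_cleavage_sites_gives_whole_sequence(self):
        assert digest("MAAAGGG") == ["MAAAGGG"]

    def test_missed_cleavage_concatenations(self):
        assert set(digest("MKAAAR", missed_cleavages=1)) == {
            "MK", "AAAR", "MKAAAR"
        }

    @given(st.text(alphabet=AA, min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_fragments_reconstruct_protein(self, protein):
        assert "".join(digest(protein)) == protein


class TestLengthFilter:
    def test_inclusive_boundaries(self):
        peptides = ["A" * 7, "A" * 8, "A" * 40, "A" * 41]
        assert length_filter(peptides) == ["A" * 8, "A" * 40]

    def test_empty_and_idempotent(self):
        assert length_filter([]) == []
        once = length_filter(["A" * 10, "A" * 50])
        assert length_filter(once) == once


class TestIsoelectricPoint:
    def test_glycine_peptide_is_terminal_midpoint(self):
        expected = (PKA_BJELLQVIST["n_term"] + PKA_BJELLQVIST["c_term"]) / 2
        assert compute_pi("GGGGG") == pytest.approx(expected, abs=1e-4)

    def test_acdk_matches_grid_scan_oracle(self):
        assert compute_pi("ACDK") == pytest.approx(
            pi_gridscan_oracle("ACDK"), abs=1e-4
        )

    @given(st.text(alphabet=AA, min_size=8, max_size=40))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_random_peptides_match_grid_scan_oracle(self, peptide):
        assert compute_pi(peptide) == pytest.approx(
            pi_gridscan_oracle(peptide), abs=1e-4
        )

    @given(st.text(alphabet=AA, min_size=1, max_size=25))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_basic_residue_raises_and_acidic_lowers_pi(self, peptide):
        base = compute_pi(peptide)
        assert compute_pi(peptide + "K") > base
        assert compute_pi(peptide + "D") < base


class TestFractionate:
    def test_wide_range_arithmetic(self):
        assert fractionate([6.5], 3.0, 10.0, 72)[0] == (37, False)

    def test_edges_clamp(self):
        assert fractionate([3.0], 3.0, 10.0, 72)[0][0] == 1
        assert fractionate([10.0], 3.0, 10.0, 72)[0][0] == 72
        idx, flagged = fractionate([2.0], 3.0, 10.0, 72)[0]
        assert idx == 1 and flagged

    def test_narrow_range_arithmetic(self):
        assert fractionate([4.3], 3.7, 4.9, 72)[0] == (37, False)

    def test_bin_widths_uniform(self):
        lo, hi, n = 3.0, 10.0, 72
        width = (hi - lo) / n
        edges = [lo + k * width for k in range(n + 1)]
        assert max(np.diff(edges)) - min(np.diff(edges)) < 1e-12
        # every probe pI lands in exactly one bin
        pis = np.linspace(3.001, 9.999, 500)
        for pi, (idx, _) in zip(pis, fractionate(pis, lo, hi, n)):
            assert edges[idx - 1] <= pi <= edges[idx] + 1e-12

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            fractionate([5.0], 10.0, 3.0, 72)


def record(seq, transcript="TX"):
    return PeptideRecord(
        sequence=seq, source_transcript_id=transcript, source_gene_id="G",
        start=0, end=len(seq), nt_start=0, nt_end=3 * len(seq),
    )


class TestCanonicalSubtraction:
    CANON = [SequenceRecord("C1", "MAAPEPTIDEKGGR", "protein")]

    def test_exact_match_removed(self):
        novel, matched = subtract_canonical([record("PEPTIDEK")], self.CANON)
        assert not novel
        assert matched[0].canonical_match == "exact"

    def test_il_equivalent_removed(self):
        novel, matched = subtract_canonical([record("PEPTLDEK")], self.CANON)
        assert not novel
        assert matched[0].canonical_match == "il_equivalent"

    def test_unmatched_retained(self):
        novel, matched = subtract_canonical([record("WWWWYYYY")], self.CANON)
        assert novel[0].canonical_match == "none"
        assert not matched


class TestSingleMismatch:
    CANON = [SequenceRecord("C1", "AAPEPTIDEGG", "protein")]

    def test_single_substitution_located(self):
        info = flag_single_mismatch(record("PEPSIDE"), self.CANON)
        assert info is not None
        assert info.peptide_position == 4
        assert info.canonical_residue == "T"
        assert info.observed_residue == "S"

    def test_two_mismatches_not_flagged(self):
        assert flag_single_mismatch(record("PEPSSDE"), self.CANON) is None

    def test_il_fold_applies(self):
        # only the I/L position differs after folding -> distance 0, no flag;
        # one real substitution on top -> distance 1
        assert flag_single_mismatch(record("PEPTLDE"), self.CANON) is None
        info = flag_single_mismatch(record("PEPSLDE"), self.CANON)
        assert info.peptide_position == 4


class TestEndToEnd:
    def test_novel_candidates_equal_planted_manifest(self, toy_transcriptome):
        transcripts, annotation, canonical, manifest = toy_transcriptome
        build = build_database(transcripts, annotation, canonical)
        got = {(p.sequence, p.novelty_class) for p in build.novel}
        want = {(m.sequence, m.novelty_class) for m in manifest}
        assert got == want

    def test_sub_tpm_transcript_contributes_nothing(self, toy_transcriptome):
        transcripts, annotation, canonical, _ = toy_transcriptome
        build = build_database(transcripts, annotation, canonical)
        low = [t.transcript_id for t in annotation if t.tpm < 1]
        assert low and not any(
            p.source_transcript_id in low for p in build.peptides
        )

    def test_tpm_boundary_inclusive(self, toy_transcriptome):
        _, annotation, _, _ = toy_transcriptome
        boundary = next(iter(annotation))
        boundary.tpm = 1.0
        assert boundary.transcript_id in filter_transcripts(annotation)
        boundary.tpm = 0.99
        assert boundary.transcript_id not in filter_transcripts(annotation)

    def test_all_retained_peptides_within_length_bounds(self, toy_transcriptome):
        transcripts, annotation, canonical, _ = toy_transcriptome
        build = build_database(transcripts, annotation, canonical)
        assert all(8 <= len(p.sequence) <= 40 for p in build.peptides)

    def test_classification_precedence_biotype_before_region(
        self, toy_transcriptome
    ):
        _, annotation, _, _ = toy_transcriptome
        pep = record("WWWWYYYY", transcript="TPS1")
        assert classify_novel(pep, annotation) == "pseudogene"
        orphan = record("WWWWYYYY", transcript="UNKNOWN")
        assert classify_novel(orphan, annotation) == "other_noncoding"
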