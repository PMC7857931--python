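"""MS1 matching, neutral-loss / diagnostic evidence, linkage and confirmation."""

import pytest

from flavonet.chem_core import ElementalFormula
from flavonet.spectral_annotation import (
    AnnotationConfig,
    ReferenceStandard,
    SpectrumRecord,
    annotate,
    classify_glycoside_linkage,
    confirm_with_standards,
    detect_neutral_losses,
    match_diagnostic_fragments,
    match_ms1,
    read_spectra_mgf,
    read_spectra_tsv,
    results_to_tsv,
    write_spectra_mgf,
    write_spectra_tsv,
)

F = ElementalFormula.parse


def _record(records, peak):
    return next(r for r in records if r.peak_id == peak)


def _candidate(library, label):
    return next(c for c in library if c.label == label)


class TestSpectrumRecord:
    def test_fragments_sorted_by_intensity(self):
        r = SpectrumRecord(1, 1.0, 500.0, 1e6, ((400.0, 10.0), (300.0, 100.0)))
        assert r.fragments[0] == (300.0, 100.0)
        assert r.base_peak_mz == 300.0

    def test_fragment_above_precursor_rejected(self):
        with pytest.raises(ValueError):
            SpectrumRecord(1, 1.0, 300.0, 1e6, ((301.0, 50.0),))

    def test_negative_rt_rejected(self):
        with pytest.raises(ValueError):
            SpectrumRecord(1, -0.5, 300.0, 1e6)


class TestMatchMs1:
    def test_taxifolin_glucoside_precursor(self, full_library, fixture_data):
        records, _ = fixture_data
        hits = match_ms1(_record(records, 3), full_library)
        assert hits, "precursor 465.1042 should match the library"
        labels = {c.label for c, _ in hits}
        assert "taxifolin-glucoside" in labels
        ppm = dict((c.label, p) for c, p in hits)["taxifolin-glucoside"]
        assert ppm == pytest.approx(0.86, abs=0.15)

    def test_intensity_floor_suppresses_matches(self, full_library, fixture_data):
        records, _ = fixture_data
        weak = SpectrumRecord(99, 1.0, records[0].precursor_mz, 9999.0)
        assert match_ms1(weak, full_library) == []

    def test_out_of_tolerance_precursor_excluded(self, full_library):
        off = SpectrumRecord(99, 1.0, 465.1062, 1e6)  # 5.16 ppm from 465.1038
        labels = {c.label for c, _ in match_ms1(off, full_library)}
        assert "taxifolin-glucoside" not in labels

    def test_sorted_by_absolute_ppm(self, full_library, fixture_data):
        records, _ = fixture_data
        hits = match_ms1(_record(records, 1), full_library)
        devs = [abs(p) for _, p in hits]
        assert devs == sorted(devs)


class TestNeutralLosses:
    def test_combined_hexose_glucuronide_loss(self, full_library, fixture_data):
        """A di-conjugate sheds both sugars at once, exposing the aglycone anion."""
        records, _ = fixture_data
        cand = _candidate(full_library, "eriodictyol-glucuronide-glucoside")
        losses = detect_neutral_losses(_record(records, 12), cand)
        combined = [m for m in losses if len(m.rule_names) == 2]
        assert combined and combined[0].observed_mz == pytest.approx(287.0558)

    def test_observed_loss_reported_from_spectrum(self, full_library, fixture_data):
        records, _ = fixture_data
        cand = _candidate(full_library, "phloretin-glucoside-pentoside")
        losses = detect_neutral_losses(_record(records, 32), cand)
        combined = next(m for m in losses if len(m.rule_names) == 2)
        assert round(combined.observed_loss, 3) == 294.096

    def test_no_fragments_gives_no_losses(self, full_library):
        cand = _candidate(full_library, "eriodictyol-glucoside")
        empty = SpectrumRecord(99, 1.0, cand.theoretical_mz, 1e6)
        assert detect_neutral_losses(empty, cand) == []

    def test_anchored_on_theoretical_precursor(self, full_library):
        """A +4 ppm precursor error must not displace expected fragment slots."""
        cand = _candidate(full_library, "eriodictyol-glucoside")
        aglycone = 287.0561
        record = SpectrumRecord(
            99, 1.0, cand.theoretical_mz * (1 + 4e-6), 1e6, ((aglycone, 100.0),)
        )
        losses = detect_neutral_losses(record, cand)
        assert losses and abs(losses[0].ppm) < 1.0

    def test_tightening_tolerance_never_adds_matches(self, full_library, fixture_data):
        records, _ = fixture_data
        cand = _candidate(full_library, "taxifolin-glucoside")
        rec = _record(records, 1)
        wide = {m.rule_names for m in detect_neutral_losses(rec, cand, tol_ppm=10)}
        tight = {m.rule_names for m in detect_neutral_losses(rec, cand, tol_ppm=2)}
        assert tight <= wide


class TestDiagnostics:
    def test_phloretin_diagnostics_in_glucuronide_peak(self, extended_skeletons, fixture_data):
        records, _ = fixture_data
        skel = {s.name: s for s in extended_skeletons}["phloretin"]
        hits = match_diagnostic_fragments(_record(records, 19), skel)
        assert len(hits) == 3  # 167.0340, 137.0233, 123.0441

    def test_taxifolin_diagnostics_in_aglycone_peak(self, extended_skeletons, fixture_data):
        records, _ = fixture_data
        skel = {s.name: s for s in extended_skeletons}["taxifolin"]
        hits = match_diagnostic_fragments(_record(records, 13), skel)
        assert len(hits) == 2  # 125.0234 (-8 ppm) and 285.0407

    def test_disjoint_fragments_give_no_hits(self, extended_skeletons):
        skel = {s.name: s for s in extended_skeletons}["phloretin"]
        record = SpectrumRecord(99, 1.0, 449.1089, 1e6, ((201.0, 100.0),))
        assert match_diagnostic_fragments(record, skel) == []


class TestLinkage:
    def test_cross_ring_pattern_is_c_glycoside(self, full_library, fixture_data):
        records, _ = fixture_data
        cand = _candidate(full_library, "apigenin-glucoside-glucoside")
        assert classify_glycoside_linkage(_record(records, 6), cand) == "C"

    def test_intact_hexose_loss_is_o_glycoside(self, full_library, fixture_data):
        records, _ = fixture_data
        cand = _candidate(full_library, "eriodictyol-glucoside")
        assert classify_glycoside_linkage(_record(records, 5), cand) == "O"

    def test_no_sugar_evidence_is_undetermined(self, full_library, fixture_data):
        records, _ = fixture_data
        cand = _candidate(full_library, "phloretin-glucuronide")
        assert classify_glycoside_linkage(_record(records, 19), cand) == "undetermined"

    def test_aglycone_candidate_rejected(self, full_library, fixture_data):
        records, _ = fixture_data
        cand = _candidate(full_library, "taxifolin")
        with pytest.raises(ValueError):
            classify_glycoside_linkage(_record(records, 13), cand)


class TestStandards:
    def test_rt_and_formula_match_confirms(self, full_library, fixture_data, standards):
        records, _ = fixture_data
        results = annotate([_record(records, 27)], full_library, standards)
        assert results[0].confidence == "standard_confirmed"
        assert results[0].standard_name == "phlorizin"

    def test_rt_mismatch_stays_characterized(self, full_library, fixture_data):
        records, _ = fixture_data
        off_rt = [ReferenceStandard("phlorizin", F("C21H24O10"), 13.2)]  # 1 min off
        results = annotate([_record(records, 27)], full_library, off_rt)
        assert results[0].confidence == "characterized"

    def test_confirm_requires_candidate(self, full_library, fixture_data, standards):
        from flavonet.spectral_annotation import AnnotationResult

        records, _ = fixture_data
        bare = AnnotationResult(99, 1.0, 500.0, None, None)
        with pytest.raises(ValueError):
            confirm_with_standards(bare, _record(records, 27), standards)

    def test_thirteen_fixture_peaks_confirmed(self, full_library, fixture_data, standards):
        records, rows = fixture_data
        results = annotate(records, full_library, standards)
        confirmed = {r.peak_id for r in results if r.confidence == "standard_confirmed"}
        expected = {row.peak for row in rows if row.standard_confirmed}
        assert confirmed == expected
        assert len(confirmed) == 13


class TestAnnotateEndToEnd:
    def test_all_fixture_peaks_annotated(self, full_library, fixture_data, standards):
        records, _ = fixture_data
        results = annotate(records, full_library, standards)
        assert len(results) == 43
        assert all(r.candidate is not None for r in results)

    def test_empty_record_list(self, full_library):
        assert annotate([], full_library) == []

    def test_deterministic_export(self, tmp_path, full_library, fixture_data, standards):
        records, _ = fixture_data
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        results_to_tsv(annotate(records, full_library, standards), out1)
        results_to_tsv(annotate(records, full_library, standards), out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_isobaric_survivors_kept_in_evidence_trail(self, full_library, fixture_data):
        records, _ = fixture_data
        results = annotate([_record(records, 20)], full_library)
        # apigenin- and baicalein-glucoside are isobaric; both must be audited
        skeletons = {e.candidate.skeleton.name for e in results[0].evidence}
        assert {"apigenin", "baicalein"} <= skeletons

    def test_radical_base_peak_separates_apigenin_from_baicalein(
        self, full_library, fixture_data
    ):
        records, _ = fixture_data
        res25 = annotate([_record(records, 25)], full_library)[0]
        res20 = annotate([_record(records, 20)], full_library)[0]
        assert res25.candidate.skeleton.name == "apigenin"
        assert res20.candidate.skeleton.name == "baicalein"
        assert res20.evidence[0].rule_derived

    def test_unmatchable_precursor_is_unannotated(self, full_library):
        stray = SpectrumRecord(99, 1.0, 999.7531, 1e6)
        result = annotate([stray], full_library)[0]
        assert result.candidate is None and result.confidence == "unannotated"


class TestPeakListIO:
    def test_tsv_round_trip(self, tmp_path, fixture_data):
        records, _ = fixture_data
        path = tmp_path / "peaks.tsv"
        write_spectra_tsv(records, path)
        back = read_spectra_tsv(path)
        assert [r.peak_id for r in back] == [r.peak_id for r in records]
        assert back[0].precursor_mz == pytest.approx(records[0].precursor_mz)
        assert len(back[0].fragments) == len(records[0].fragments)

    def test_mgf_round_trip(self, tmp_path, fixture_data):
        records, _ = fixture_data
        path = tmp_path / "peaks.mgf"
        write_spectra_mgf(records, path)
        back = read_spectra_mgf(path)
        assert len(back) == len(records)
        assert back[5].rt == pytest.approx(records[5].rt, abs=1e-6)
        assert back[5].precursor_mz == pytest.approx(records[5].precursor_mz, abs=1e-4)

    def test_malformed_tsv_names_the_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("peak_id\trt_min\tprecursor_mz\tintensity\tfragments\nnope\n")
        with pytest.raises(ValueError, match="bad.tsv:2"):
            read_spectra_tsv(path)
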