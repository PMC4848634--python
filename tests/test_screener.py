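"""The screening decision procedure: gate, evidence, exocyclic call,
library matching, novel naming, CYP flag and the fraction report."""

import numpy as np
import pytest

from anapept import masses
from anapept.scaffold import DEFAULT_CYP_DIAGNOSTIC_MZS
from anapept.screener import (
    AP_FRAGMENT_LABEL,
    ScreenConfig,
    collect_evidence,
    gate_lys,
    infer_exocyclic,
    score_library_match,
    screen,
    screen_fractions,
)
from anapept.simulate import SpectrumSimParams, simulate_decoy, simulate_spectrum
from anapept.spectra import Spectrum, Tolerance


def spectrum_of(peaks, precursor=837.4617, fraction="", sid="s"):
    return Spectrum(id=sid, precursor_mz=precursor, peaks=tuple(peaks), fraction=fraction)


class TestGate:
    def test_synthetic_ap_b_passes(self, noiseless_spectrum, cfg):
        assert gate_lys(noiseless_spectrum("AP B"), cfg)

    def test_decoy_fails(self, cfg):
        decoy = simulate_decoy(SpectrumSimParams(seed=7, n_noise_peaks=50))
        assert not gate_lys(decoy, cfg)

    def test_peak_just_outside_tolerance_fails(self, cfg):
        s = spectrum_of([(85.0, 1e5)])
        assert abs(85.0 - masses.lys_marker_mz()) > 0.5
        assert not gate_lys(s, cfg)


class TestEvidence:
    def test_ap_b_has_all_four_diagnostics(self, noiseless_spectrum, cfg):
        ev = collect_evidence(noiseless_spectrum("AP B"), cfg)
        assert ev == {"lys_marker", "phe_immonium", "arg_175", "arg_201"}

    def test_ap_a_lacks_arg_labels(self, noiseless_spectrum, cfg):
        ev = collect_evidence(noiseless_spectrum("AP A"), cfg)
        assert "arg_175" not in ev and "arg_201" not in ev
        assert {"lys_marker", "phe_immonium"} <= ev

    def test_empty_peak_list_gives_empty_set(self, cfg):
        assert collect_evidence(spectrum_of([]), cfg) == frozenset()


class TestExocyclicInference:
    def test_delta_200_calls_arg(self, cfg):
        s = spectrum_of([(637.3708, 1e4)], precursor=837.4617)
        assert infer_exocyclic(s, cfg) == "Arg"

    def test_delta_181_calls_tyr(self, cfg):
        s = spectrum_of([(663.350, 1e4)], precursor=844.4239)
        assert infer_exocyclic(s, cfg) == "Tyr"

    def test_no_loss_is_undetermined(self, cfg):
        s = spectrum_of([(84.0808, 1e4)], precursor=837.4617)
        assert infer_exocyclic(s, cfg) == "undetermined"

    def test_both_losses_resolved_by_intensity(self, cfg):
        prec = 900.0
        arg_loss = masses.residue_mass("R") + masses.H2O + masses.CO - masses.H2
        tyr_loss = masses.residue_mass("Y") + masses.H2O
        s = spectrum_of(
            [(prec - arg_loss, 10.0), (prec - tyr_loss, 1000.0)], precursor=prec
        )
        assert infer_exocyclic(s, cfg) == "Tyr"


class TestLibraryScore:
    def test_noiseless_self_match_is_one(self, noiseless_spectrum, library_by_name, cfg):
        s = noiseless_spectrum("AP B")
        assert score_library_match(s, library_by_name["AP B"], cfg) == 1.0

    def test_precursor_mismatch_scores_zero(self, noiseless_spectrum, library_by_name, cfg):
        s = noiseless_spectrum("AP B")  # precursor 837.46 vs AP A 844.42
        assert score_library_match(s, library_by_name["AP A"], cfg) == 0.0

    def test_dropout_half_gives_binomial_score(self, library_by_name, cfg):
        c = library_by_name["AP B"]
        rng = np.random.default_rng(11)
        p = SpectrumSimParams(mz_sigma=0.0, dropout_p=0.5, n_noise_peaks=0, seed=11)
        scores = [
            score_library_match(simulate_spectrum(c, p, rng=rng), c, cfg)
            for _ in range(300)
        ]
        n_frag = 14  # non-precursor predicted entries of AP B
        se = np.sqrt(0.25 / n_frag / len(scores))
        assert np.mean(scores) == pytest.approx(0.5, abs=4 * se)


class TestScreen:
    def test_named_ap_verdicts_on_noiseless_library(self, noiseless_spectrum, library):
        for c in library:
            a = screen(noiseless_spectrum(c.name), library)
            assert a.verdict == "named_ap"
            assert a.proposed_name == c.name

    def test_novel_ap_named_from_precursor(self, library, cfg):
        prec = 803.455
        arg_loss = masses.residue_mass("R") + masses.H2O + masses.CO - masses.H2
        s = spectrum_of(
            [(masses.lys_marker_mz(), 1e5), (prec - arg_loss, 1e4)], precursor=prec
        )
        a = screen(s, library, cfg)
        assert a.verdict == "novel_ap"
        assert a.proposed_name == "AP 802"
        assert a.exocyclic == "Arg"

    def test_decoy_is_none(self, library, cfg):
        a = screen(simulate_decoy(SpectrumSimParams(seed=3, n_noise_peaks=40)), library, cfg)
        assert a.verdict == "none"

    def test_cyp_flag_without_gate(self, library, cfg):
        s = spectrum_of([(DEFAULT_CYP_DIAGNOSTIC_MZS[0], 1e4)], precursor=900.0)
        a = screen(s, library, cfg)
        assert a.verdict == "cyp_like"

    def test_gate_is_a_precondition_for_ap_verdicts(self, library, cfg):
        # full diagnostic complement except the gate ion: still no AP verdict
        prec = 837.4617
        arg_loss = masses.residue_mass("R") + masses.H2O + masses.CO - masses.H2
        s = spectrum_of(
            [(120.0808, 1e4), (175.119, 1e4), (prec - arg_loss, 1e4)], precursor=prec
        )
        a = screen(s, library, cfg)
        assert a.verdict not in ("named_ap", "novel_ap")

    def test_noiseless_precision_and_recall_are_one(self, library, noiseless_params):
        rng = np.random.default_rng(5)
        truth, predictions = [], []
        for c in library:
            for _ in range(5):
                s = simulate_spectrum(c, noiseless_params, rng=rng)
                truth.append(c.name)
                predictions.append(screen(s, library).proposed_name)
        for _ in range(20):
            d = simulate_decoy(SpectrumSimParams(seed=int(rng.integers(2**31)), n_noise_peaks=30), rng=rng)
            truth.append("")
            predictions.append(screen(d, library).proposed_name)
        assert predictions == truth

    def test_dropout_monotonicity_in_named_verdicts(self, library):
        """More fragment dropout never yields more named-AP calls (in
        expectation over a fixed seed set)."""
        def n_named(dropout):
            total = 0
            for seed in range(40):
                rng = np.random.default_rng(seed)
                p = SpectrumSimParams(mz_sigma=0.0, dropout_p=dropout, n_noise_peaks=0, seed=seed)
                for c in library:
                    if screen(simulate_spectrum(c, p, rng=rng), library).verdict == "named_ap":
                        total += 1
            return total

        counts = [n_named(d) for d in (0.0, 0.3, 0.6, 0.9)]
        assert counts == sorted(counts, reverse=True)


class TestScreenFractions:
    def test_permutation_invariance(self, library, noiseless_spectrum):
        spectra = [
            noiseless_spectrum("AP A", fraction="20% MeOH"),
            noiseless_spectrum("AP B", fraction="40% MeOH"),
            noiseless_spectrum("OSC Y", fraction="30% MeOH"),
        ]
        fwd = screen_fractions(spectra, library)
        rev = screen_fractions(spectra[::-1], library)
        assert fwd.table.equals(rev.table)
        assert fwd.distinct_aps == rev.distinct_aps

    def test_duplicate_rows_collapse(self, library, noiseless_spectrum):
        spectra = [noiseless_spectrum("AP A", fraction="20% MeOH") for _ in range(3)]
        report = screen_fractions(spectra, library)
        assert len(report.table) == 1

    def test_ring_fragment_precursor_reported_as_fragment(self, library, cfg):
        s = spectrum_of([(84.0808, 1e4)], precursor=637.3708, fraction="70% MeOH")
        report = screen_fractions([s], library, cfg)
        assert list(report.table.proposed_name) == [AP_FRAGMENT_LABEL]
        assert report.n_distinct_aps == 0

    def test_empty_input_empty_report(self, library):
        report = screen_fractions([], library)
        assert report.table.empty
        assert report.n_distinct_aps == 0

    def test_fractions_sorted_numerically(self, library, noiseless_spectrum):
        spectra = [
            noiseless_spectrum("AP A", fraction="100% MeOH"),
            noiseless_spectrum("AP A", fraction="20% MeOH"),
        ]
        report = screen_fractions(spectra, library)
        assert list(report.table.fraction) == ["20% MeOH", "100% MeOH"]
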