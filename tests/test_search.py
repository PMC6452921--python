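"""Crosslink search: candidate index, fragments, scoring, FDR, deduplication."""

import numpy as np
import pytest
from pyteomics.mass import std_aa_mass

from trappkit.chem import PROTON_MASS, make_adduct
from trappkit.digest import PeptideCandidate, ProteinRecord, tryptic_digest
from trappkit.search import (
    CandidateIndex,
    CrosslinkPSM,
    SearchConfig,
    SpectrumRecord,
    compute_fdr,
    deduplicate_psms,
    score_psm,
    search_spectrum,
    theoretical_fragments,
)
from trappkit.simulate import SpectrumSimConfig, simulate_conjugate_spectrum


def _candidate(seq, protein="prot", start=1, decoy=False):
    mass = sum(std_aa_mass[a] for a in seq) + 18.0105646863
    return PeptideCandidate(seq, protein, start, 0, mass, is_decoy=decoy)


@pytest.fixture(scope="module")
def adduct():
    return make_adduct(("4tU",), "none")


class TestCandidateIndex:
    def test_one_peptide_six_adducts(self, mono_adducts):
        idx = CandidateIndex([_candidate("PEPTIDEK")], mono_adducts)
        assert len(idx) == 6

    def test_window_query_returns_entry(self, mono_adducts):
        pep = _candidate("PEPTIDEK")
        idx = CandidateIndex([pep], mono_adducts)
        mass = pep.mass + mono_adducts[0].precursor_mass
        hits = idx.query(mass, 6.0)
        assert (pep, mono_adducts[0]) in hits

    def test_agrees_with_linear_scan(self, rng, mono_adducts):
        peptides = [
            _candidate("".join(rng.choice(list("ACDEFGHILMNPQSTVWY"), rng.integers(6, 15))) + "K")
            for _ in range(200)
        ]
        idx = CandidateIndex(peptides, mono_adducts)
        for _ in range(50):
            center = float(rng.uniform(800, 2500))
            got = set(
                (id(p), a.label) for p, a in idx.query(center, 20.0)
            )
            tol = center * 20e-6
            expected = set(
                (id(p), a.label)
                for p in peptides
                for a in mono_adducts
                if abs(p.mass + a.precursor_mass - center) <= tol
            )
            assert got == expected


class TestTheoreticalFragments:
    def test_backbone_count_before_expansion(self, adduct):
        pep = _candidate("PEPTIDEK")
        frags = theoretical_fragments(pep, adduct, site=4, config=SearchConfig(max_fragment_charge=1))
        backbone = {(f.series, f.index) for f in frags}
        assert len(backbone) == 2 * (len(pep.sequence) - 1)

    def test_site_one_only_b_ions_carry_stubs(self, adduct):
        frags = theoretical_fragments(_candidate("PEPTIDEK"), adduct, site=1)
        stub_series = {f.series for f in frags if f.stub_mass > 0}
        assert stub_series == {"b"}

    def test_site_last_only_y_ions_carry_stubs(self, adduct):
        frags = theoretical_fragments(_candidate("PEPTIDEK"), adduct, site=8)
        stub_series = {f.series for f in frags if f.stub_mass > 0}
        assert stub_series == {"y"}

    def test_span_membership_matches_positional_oracle(self, adduct):
        seq = "PEPTIDESK"
        n = len(seq)
        for site in range(1, n + 1):
            frags = theoretical_fragments(_candidate(seq), adduct, site=site)
            for f in frags:
                residues = set(range(1, f.index + 1)) if f.series == "b" else set(
                    range(n - f.index + 1, n + 1)
                )
                if f.stub_mass > 0:
                    assert site in residues
                # no-stub fragments exist for spanning ions too (complete loss)

    def test_b2_mz_matches_hand_sum(self, adduct):
        # b2 of "AK" at charge 1: Ala + Lys residues + proton
        frags = theoretical_fragments(_candidate("AKAAAK"), adduct, site=6)
        b2 = [f for f in frags if f.series == "b" and f.index == 2 and f.charge == 1
              and f.stub_mass == 0 and f.neutral_loss == "none"]
        expected = std_aa_mass["A"] + std_aa_mass["K"] + PROTON_MASS
        assert b2[0].mz == pytest.approx(expected, abs=1e-6)

    def test_invalid_site_rejected(self, adduct):
        with pytest.raises(ValueError):
            theoretical_fragments(_candidate("PEPTIDEK"), adduct, site=9)


class TestScoring:
    def test_perfect_spectrum_full_coverage(self, adduct):
        pep = _candidate("PEPTIDEK")
        frags = theoretical_fragments(pep, adduct, site=4)
        mz = np.unique([f.mz for f in frags])
        spectrum = SpectrumRecord("s", 500.0, 2, mz, np.ones_like(mz))
        score, coverage, k = score_psm(spectrum, frags, n_bonds=len(pep.sequence) - 1)
        assert coverage == 1.0
        assert k == len(mz)
        assert score > 50

    def test_empty_spectrum_scores_zero(self, adduct):
        frags = theoretical_fragments(_candidate("PEPTIDEK"), adduct, site=4)
        spectrum = SpectrumRecord("s", 500.0, 2, np.array([]), np.array([]))
        assert score_psm(spectrum, frags) == (0.0, 0.0, 0)

    def test_adding_matched_peak_never_decreases_score(self, adduct):
        pep = _candidate("PEPTIDESK")
        frags = theoretical_fragments(pep, adduct, site=3)
        frag_mz = np.unique([f.mz for f in frags])
        rng = np.random.default_rng(0)
        base_mz = np.sort(rng.uniform(100, 1500, 60))
        prev = -1.0
        for extra in range(0, 20, 4):
            mz = np.sort(np.concatenate([base_mz, frag_mz[:extra]]))
            spectrum = SpectrumRecord("s", 500.0, 2, mz, np.ones_like(mz))
            score, _, _ = score_psm(spectrum, frags)
            assert score >= prev - 1e-6
            prev = score

    def test_random_spectrum_match_rate_calibrated(self, adduct):
        # mean distinct-peak matches over random spectra ~ N*p
        pep = _candidate("PEPTIDESK")
        frags = theoretical_fragments(pep, adduct, site=3)
        frag_mz = np.array([f.mz for f in frags])
        config = SearchConfig(allow_off_by_one=False)
        rng = np.random.default_rng(11)
        n_peaks, lo, hi = 200, 100.0, 1800.0
        counts = []
        for _ in range(200):
            mz = np.sort(rng.uniform(lo, hi, n_peaks))
            spectrum = SpectrumRecord("s", 500.0, 2, mz, np.ones_like(mz))
            _, _, k = score_psm(spectrum, frags, config=config)
            counts.append(k)
        density = n_peaks / (hi - lo)
        # expectation from the merged union of tolerance windows (windows of
        # duplicate/near-duplicate fragments overlap)
        tol = config.ms2_tol_ppm * 1e-6
        intervals = sorted((m * (1 - tol), m * (1 + tol)) for m in frag_mz)
        union = 0.0
        cur_lo, cur_hi = intervals[0]
        for a, b in intervals[1:]:
            if a > cur_hi:
                union += cur_hi - cur_lo
                cur_lo, cur_hi = a, b
            else:
                cur_hi = max(cur_hi, b)
        union += cur_hi - cur_lo
        expected = union * density
        se = np.sqrt(expected / 200)  # Poisson-ish Monte-Carlo error
        assert abs(np.mean(counts) - expected) < 4 * se + 0.05 * expected


class TestSearchSpectrum:
    def test_planted_noiseless_spectrum_recovered(self, search_index, search_db, mono_adducts):
        targets = [p for p in search_db if not p.is_decoy and 8 <= len(p.sequence) <= 14]
        pep, ad, site = targets[5], mono_adducts[2], 4
        cfg = SpectrumSimConfig(detection_prob=1.0, n_noise_peaks=0, ppm_error=0.0)
        spectrum, _ = simulate_conjugate_spectrum(pep, ad, site, cfg)
        hits = search_spectrum(spectrum, search_index)
        assert hits
        best = hits[0]
        assert best.peptide.sequence == pep.sequence
        assert best.adduct.label == ad.label
        assert best.site == site
        assert not best.is_decoy

    def test_far_precursor_returns_empty(self, search_index):
        mass = search_index.masses[0] * (1 + 50e-6)
        spectrum = SpectrumRecord("s", (mass + 2 * PROTON_MASS) / 2, 2,
                                  np.array([300.0]), np.array([1.0]))
        assert search_spectrum(spectrum, search_index) == []

    def test_charge_outside_range_skipped(self, search_index):
        mass = search_index.masses[0]
        spectrum = SpectrumRecord("s", mass + PROTON_MASS, 1,
                                  np.array([300.0]), np.array([1.0]))
        assert search_spectrum(spectrum, search_index) == []

    def test_no_stub_ions_means_undefined_site(self, adduct):
        # spectrum with only non-stub backbone fragments cannot localize
        pep = _candidate("LDGYNEVSK")
        config = SearchConfig(max_fragment_charge=1, max_neutral_losses=0,
                              allow_off_by_one=False)
        index = CandidateIndex([pep], [adduct])
        frags = theoretical_fragments(pep, adduct, site=1, config=config)
        mz = np.unique([f.mz for f in frags if f.stub_mass == 0])
        z = 2
        precursor = (pep.mass + adduct.precursor_mass + z * PROTON_MASS) / z
        spectrum = SpectrumRecord("s", precursor, z, mz, np.ones_like(mz))
        hits = search_spectrum(spectrum, index, config)
        assert hits and hits[0].peptide.sequence == pep.sequence
        assert hits[0].site is None


class TestFdr:
    def _psms(self, flags, scores=None):
        scores = scores or list(range(len(flags), 0, -1))
        return [
            CrosslinkPSM(f"s{i}", _candidate("PEPTIDEK", decoy=d), make_adduct(("4tU",)),
                         1, float(s), d, 0.5, 3)
            for i, (d, s) in enumerate(zip(flags, scores))
        ]

    def test_hand_computed_running_fdr(self):
        # score order: T T T T D T
        res = compute_fdr(self._psms([False] * 4 + [True, False]), threshold=0.5)
        assert res.running_fdr[4] == pytest.approx(1 / 4)
        assert res.running_fdr[5] == pytest.approx(1 / 5)

    def test_all_targets_accepted(self):
        res = compute_fdr(self._psms([False] * 5), threshold=0.01)
        assert len(res.accepted) == 5

    def test_all_decoys_accept_nothing(self):
        res = compute_fdr(self._psms([True] * 4), threshold=0.1)
        assert res.accepted == []

    def test_q_values_monotone_in_rank(self):
        rng = np.random.default_rng(5)
        flags = list(rng.random(40) < 0.4)
        scores = list(rng.uniform(0, 10, 40))
        res = compute_fdr(self._psms(flags, scores), threshold=0.05)
        assert (np.diff(res.q_values) >= -1e-12).all()

    def test_tied_scores_rank_decoys_first(self):
        res = compute_fdr(self._psms([False, True], scores=[5.0, 5.0]), threshold=0.9)
        assert res.psms[0].is_decoy


class TestDeduplication:
    def _psm(self, protein, start, site, score, seq="PEPTIDEK", adduct_mod="none"):
        pep = _candidate(seq, protein=protein, start=start)
        return CrosslinkPSM("s", pep, make_adduct(("4tU",), adduct_mod), site, score, False, 0.5, 3)

    def test_same_residue_keeps_best_score(self):
        sites = deduplicate_psms([self._psm("p", 10, 3, 10.0), self._psm("p", 10, 3, 12.0)])
        assert len(sites) == 1
        assert sites[0].score == 12.0
        assert sites[0].position == 12  # absolute: start 10 + site 3 - 1

    def test_single_psm_passes_through(self):
        sites = deduplicate_psms([self._psm("p", 1, 2, 5.0)])
        assert len(sites) == 1
        assert sites[0].amino_acid == "E"

    def test_undefined_sites_dropped(self):
        psms = [self._psm("p", 1, 2, 5.0),
                CrosslinkPSM("s", _candidate("PEPTIDEK"), make_adduct(("4tU",)), None, 9.0,
                             False, 0.5, 3)]
        assert len(deduplicate_psms(psms)) == 1

    def test_same_peptide_same_rna_collapsed(self):
        # two residues of the same peptide+adduct: keep the higher score
        sites = deduplicate_psms([self._psm("p", 1, 2, 5.0), self._psm("p", 1, 4, 7.0)])
        assert len(sites) == 1 and sites[0].position == 4

    def test_distinct_sites_all_reported(self):
        psms = [self._psm("p1", 1, 2, 5.0), self._psm("p2", 1, 3, 6.0, seq="CCCEEEK"),
                self._psm("p1", 30, 4, 7.0, seq="AAADDDK")]
        assert len(deduplicate_psms(psms)) == 3

    def test_shared_peptide_same_rna_across_proteins_collapsed(self):
        # the same peptide+adduct observed at two residues of two proteins is
        # one crosslink after the peptide/RNA duplicate filter
        psms = [self._psm("p1", 1, 2, 5.0), self._psm("p2", 1, 3, 6.0)]
        sites = deduplicate_psms(psms)
        assert len(sites) == 1 and sites[0].score == 6.0


def test_search_deterministic(search_index, search_db, mono_adducts):
    targets = [p for p in search_db if not p.is_decoy and 8 <= len(p.sequence) <= 14]
    cfg = SpectrumSimConfig(detection_prob=0.7, n_noise_peaks=30, ppm_error=5.0, seed=8)
    spectrum, _ = simulate_conjugate_spectrum(targets[0], mono_adducts[1], 3, cfg)
    a = search_spectrum(spectrum, search_index)
    b = search_spectrum(spectrum, search_index)
    assert a == b
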