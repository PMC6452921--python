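"""Crosslink spectrum search: match MS2 spectra to peptide + RNA-adduct candidates.

The search treats the RNA adduct as a cleavable molecule: peptide backbone
fragments (b/y ions) that span the crosslinked residue are considered with the
adduct fully lost, fully retained, or reduced to one of the eight 4tU-derived
stub masses.  Candidates within the MS1 tolerance of the uncharged precursor
mass are scored at every possible crosslink site; targets and decoys compete
in the same search, and the accepted set is controlled by target/decoy FDR
(decoy/target ratio on the score-sorted PSM list).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import betainc, gammaln, logsumexp

from .chem import F, PROTON_MASS, RnaAdduct, monoisotopic_mass
from .digest import PeptideCandidate, residue_masses

__all__ = [
    "SpectrumRecord",
    "SearchConfig",
    "TheoreticalFragment",
    "CrosslinkPSM",
    "CrosslinkSite",
    "FdrResult",
    "CandidateIndex",
    "build_candidate_index",
    "theoretical_fragments",
    "score_psm",
    "search_spectrum",
    "run_search",
    "compute_fdr",
    "deduplicate_psms",
]

WATER = monoisotopic_mass(F("H2O"))
AMMONIA = monoisotopic_mass(F("NH3"))
NEUTRON_SPACING = 1.00335483  # C13-C12 spacing used for the +-1 Da option

_H2O_LOSS_RESIDUES = set("STED")
_NH3_LOSS_RESIDUES = set("RKNQ")


@dataclass(frozen=True)
class SpectrumRecord:
    """One MS2 spectrum: precursor and an m/z-sorted peak list."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError("precursor charge must be >= 1")
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])

    def neutral_mass(self) -> float:
        return self.charge * self.precursor_mz - self.charge * PROTON_MASS


@dataclass(frozen=True)
class SearchConfig:
    ms1_tol_ppm: float = 6.0
    ms2_tol_ppm: float = 20.0
    max_missed_cleavages: int = 2
    min_peptide_length: int = 6
    min_charge: int = 2
    max_charge: int = 7
    max_fragment_charge: int = 2
    max_neutral_losses: int = 1
    allow_off_by_one: bool = True
    fdr_threshold: float = 0.01

    def __post_init__(self):
        if self.ms1_tol_ppm <= 0 or self.ms2_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("FDR threshold must be in (0, 1)")


@dataclass(frozen=True)
class TheoreticalFragment:
    series: str  # "b" or "y"
    index: int
    charge: int
    stub_mass: float  # 0.0 = adduct fully lost; may be the full adduct mass
    neutral_loss: str  # "none" | "H2O" | "NH3"
    mz: float


@dataclass(frozen=True)
class CrosslinkPSM:
    spectrum_id: str
    peptide: PeptideCandidate
    adduct: RnaAdduct
    site: int | None  # 1-based within peptide; None = undefined localization
    score: float
    is_decoy: bool
    coverage: float
    matched_peaks: int


@dataclass(frozen=True)
class CrosslinkSite:
    """A unique crosslink site after FDR filtering and deduplication."""

    protein_id: str
    position: int  # 1-based absolute residue position in the protein
    amino_acid: str
    adduct_label: str
    score: float
    peptide_sequence: str = ""
    missed_cleavages: int = 0


@dataclass
class FdrResult:
    psms: list[CrosslinkPSM]  # sorted by descending score (decoys first on ties)
    running_fdr: np.ndarray
    q_values: np.ndarray
    accepted: list[CrosslinkPSM]
    score_threshold: float


class CandidateIndex:
    """Precursor-mass-sorted index over (peptide, adduct) pairs."""

    def __init__(self, peptides: list[PeptideCandidate], adducts: list[RnaAdduct]):
        if not peptides or not adducts:
            raise ValueError("peptides and adducts must be non-empty")
        pairs = [(p, a) for p in peptides for a in adducts]
        masses = np.array([p.mass + a.precursor_mass for p, a in pairs])
        order = np.argsort(masses, kind="stable")
        self.masses = masses[order]
        self.pairs = [pairs[i] for i in order]

    def __len__(self) -> int:
        return len(self.pairs)

    def query(self, neutral_mass: float, tol_ppm: float) -> list[tuple[PeptideCandidate, RnaAdduct]]:
        delta = neutral_mass * tol_ppm * 1e-6
        lo = np.searchsorted(self.masses, neutral_mass - delta, side="left")
        hi = np.searchsorted(self.masses, neutral_mass + delta, side="right")
        return self.pairs[lo:hi]


def build_candidate_index(peptides: list[PeptideCandidate], adducts: list[RnaAdduct]) -> CandidateIndex:
    return CandidateIndex(peptides, adducts)


def _stub_options(adduct: RnaAdduct) -> np.ndarray:
    # {complete loss} U {full adduct} U retained-stub set, deduplicated
    stubs = [0.0, adduct.precursor_mass, *adduct.stub_masses]
    return np.unique(np.round(np.array(stubs), 6))


class _CandidateFragments:
    """Per-(peptide, adduct) fragment machinery, shared across candidate sites.

    Backbone b_i / y_j neutral masses and loss applicability depend only on the
    peptide; only stub-bearing (site-spanning) fragments depend on the site, so
    the no-stub block is built once.
    """

    def __init__(self, peptide: PeptideCandidate, adduct: RnaAdduct, config: SearchConfig):
        self.peptide = peptide
        self.adduct = adduct
        self.config = config
        seq = peptide.sequence
        n = len(seq)
        res = residue_masses(peptide)
        prefix = np.concatenate([[0.0], np.cumsum(res)])
        # b_i spans residues 1..i, y_j spans residues n-j+1..n
        idx = np.arange(1, n)
        self.b_neutral = prefix[idx]
        self.y_neutral = prefix[n] - prefix[n - idx] + WATER
        in_h2o = np.array([aa in _H2O_LOSS_RESIDUES for aa in seq])
        in_nh3 = np.array([aa in _NH3_LOSS_RESIDUES for aa in seq])
        cum_h2o = np.concatenate([[False], np.cumsum(in_h2o) > 0])
        cum_nh3 = np.concatenate([[False], np.cumsum(in_nh3) > 0])
        rev_h2o = np.concatenate([[False], np.cumsum(in_h2o[::-1]) > 0])
        rev_nh3 = np.concatenate([[False], np.cumsum(in_nh3[::-1]) > 0])
        self.b_h2o = cum_h2o[idx]
        self.b_nh3 = cum_nh3[idx]
        self.y_h2o = rev_h2o[idx]
        self.y_nh3 = rev_nh3[idx]
        self.n = n
        # bond index supported by each fragment: b_i -> bond i, y_j -> bond n-j
        self.b_bond = idx
        self.y_bond = n - idx
        self.stubs = _stub_options(adduct)
        self._base = self._expand(
            np.concatenate([self.b_neutral, self.y_neutral]),
            np.concatenate([self.b_bond, self.y_bond]),
            np.concatenate([self.b_h2o, self.y_h2o]),
            np.concatenate([self.b_nh3, self.y_nh3]),
            stub=0.0,
        )

    def _expand(self, neutral, bond, h2o_ok, nh3_ok, stub=0.0):
        """Expand neutral fragment masses over charges and <=1 neutral loss."""
        cfg = self.config
        mz_parts, z_parts, bond_parts = [], [], []
        losses = [("none", 0.0, None)]
        if cfg.max_neutral_losses >= 1:
            losses += [("H2O", WATER, h2o_ok), ("NH3", AMMONIA, nh3_ok)]
        for z in range(1, cfg.max_fragment_charge + 1):
            for _, delta, mask in losses:
                sel = slice(None) if mask is None else mask
                nm = neutral[sel] + stub - delta
                mz_parts.append((nm + z * PROTON_MASS) / z)
                z_parts.append(np.full(len(nm), float(z)))
                bond_parts.append(bond[sel])
        return (
            np.concatenate(mz_parts),
            np.concatenate(z_parts),
            np.concatenate(bond_parts),
        )

    def site_arrays(self, site: int):
        """(mz, charge, bond, is_stub) arrays for a given crosslink site."""
        n = self.n
        if not (1 <= site <= n):
            raise ValueError(f"invalid crosslink site {site} for peptide length {n}")
        b_span = self.b_bond >= site  # b_i contains site iff i >= site
        y_span = self.y_bond < site  # y_j contains site iff n-j+1 <= site
        span_neutral = np.concatenate([self.b_neutral[b_span], self.y_neutral[y_span]])
        span_bond = np.concatenate([self.b_bond[b_span], self.y_bond[y_span]])
        span_h2o = np.concatenate([self.b_h2o[b_span], self.y_h2o[y_span]])
        span_nh3 = np.concatenate([self.b_nh3[b_span], self.y_nh3[y_span]])
        mz0, z0, bond0 = self._expand(span_neutral, span_bond, span_h2o, span_nh3)
        stubs_nz = self.stubs[self.stubs != 0.0]
        # broadcast stub shifts (stub mass / charge) over the spanning block
        stub_mz = (mz0[None, :] + stubs_nz[:, None] / z0[None, :]).ravel()
        k = len(stubs_nz)
        mz = np.concatenate([self._base[0], stub_mz])
        z = np.concatenate([self._base[1], np.tile(z0, k)])
        bond = np.concatenate([self._base[2], np.tile(bond0, k)])
        is_stub = np.zeros(len(mz), dtype=bool)
        is_stub[len(self._base[0]):] = True
        return mz, z, bond, is_stub

    def full_arrays(self):
        """Site-independent (mz, charge, bond, is_b, ion_index, is_stub) arrays.

        The stub block expands *every* backbone fragment with every nonzero
        stub; per-site scoring selects the base block plus the stub-block rows
        whose fragment spans the site.
        """
        if not hasattr(self, "_full"):
            all_neutral = np.concatenate([self.b_neutral, self.y_neutral])
            all_bond = np.concatenate([self.b_bond, self.y_bond])
            all_h2o = np.concatenate([self.b_h2o, self.y_h2o])
            all_nh3 = np.concatenate([self.b_nh3, self.y_nh3])
            n_b = len(self.b_neutral)
            all_is_b = np.arange(len(all_neutral)) < n_b
            all_index = np.concatenate(
                [np.arange(1, n_b + 1), np.arange(1, len(self.y_neutral) + 1)]
            )
            # _expand over charges/losses, carrying is_b/index through the
            # same selection pattern (bond trick: encode row id as "bond")
            row_id = np.arange(len(all_neutral))
            mz0, z0, rid0 = self._expand(all_neutral, row_id, all_h2o, all_nh3)
            rid0 = rid0.astype(int)
            stubs_nz = self.stubs[self.stubs != 0.0]
            k = len(stubs_nz)
            stub_mz = (mz0[None, :] + stubs_nz[:, None] / z0[None, :]).ravel()
            mz = np.concatenate([mz0, stub_mz])
            z = np.concatenate([z0, np.tile(z0, k)])
            rid = np.concatenate([rid0, np.tile(rid0, k)])
            is_stub = np.zeros(len(mz), dtype=bool)
            is_stub[len(mz0):] = True
            self._full = (
                mz,
                z,
                all_bond[rid],
                all_is_b[rid],
                all_index[rid],
                is_stub,
            )
        return self._full


@lru_cache(maxsize=4096)
def _candidate_fragments_cached(
    peptide: PeptideCandidate, adduct: RnaAdduct, config: SearchConfig
) -> "_CandidateFragments":
    return _CandidateFragments(peptide, adduct, config)


def theoretical_fragments(
    peptide: PeptideCandidate,
    adduct: RnaAdduct,
    site: int,
    config: SearchConfig = SearchConfig(),
) -> list[TheoreticalFragment]:
    """Enumerate theoretical b/y fragments for a peptide crosslinked at ``site``.

    Fragments spanning the site are emitted once per stub mass in
    {complete loss, full adduct} U retained-stub set; fragments not spanning
    the site carry no stub.  At most one neutral loss (H2O / NH3, gated on
    residue content) per fragment; fragment charges 1..max_fragment_charge.
    """
    cand = _CandidateFragments(peptide, adduct, config)
    n = len(peptide.sequence)
    if not (1 <= site <= n):
        raise ValueError(f"invalid crosslink site {site} for peptide length {n}")
    out = []
    losses = [("none", 0.0)]
    if config.max_neutral_losses >= 1:
        losses += [("H2O", WATER), ("NH3", AMMONIA)]
    for series, neutrals, h2o_ok, nh3_ok in (
        ("b", cand.b_neutral, cand.b_h2o, cand.b_nh3),
        ("y", cand.y_neutral, cand.y_h2o, cand.y_nh3),
    ):
        for k, neutral in enumerate(neutrals):
            index = k + 1
            if series == "b":
                spans = index >= site
            else:
                spans = n - index + 1 <= site
            stubs = cand.stubs if spans else np.array([0.0])
            for stub in stubs:
                for loss_name, loss_delta in losses:
                    if loss_name == "H2O" and not h2o_ok[k]:
                        continue
                    if loss_name == "NH3" and not nh3_ok[k]:
                        continue
                    for z in range(1, config.max_fragment_charge + 1):
                        mz = (neutral + stub - loss_delta + z * PROTON_MASS) / z
                        out.append(
                            TheoreticalFragment(series, index, z, float(stub), loss_name, mz)
                        )
    return out


def _all_hits(peak_mz, frag_mz, frag_z, tol_ppm, off_by_one):
    """All (fragment, peak) hits within the ppm window.

    Each query (fragment m/z, optionally +-1 neutron / z) contributes at most
    one peak.  Returns (owner fragment index, peak index) arrays.
    """
    if len(peak_mz) == 0 or len(frag_mz) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    queries = [frag_mz]
    owners = [np.arange(len(frag_mz))]
    if off_by_one:
        for sign in (-1.0, 1.0):
            queries.append(frag_mz + sign * NEUTRON_SPACING / frag_z)
            owners.append(np.arange(len(frag_mz)))
    q = np.concatenate(queries)
    owner = np.concatenate(owners)
    tol = q * tol_ppm * 1e-6
    idx = np.searchsorted(peak_mz, q)
    matched = np.zeros(len(q), dtype=bool)
    peak_idx = np.full(len(q), -1, dtype=int)
    for shift in (0, -1):
        j = idx + shift
        ok = (j >= 0) & (j < len(peak_mz))
        hit = ok.copy()
        hit[ok] = np.abs(peak_mz[j[ok]] - q[ok]) <= tol[ok]
        newly = hit & ~matched
        matched |= hit
        peak_idx[newly] = j[newly]
    return owner[matched], peak_idx[matched]


def _match_arrays(peak_mz, frag_mz, frag_z, tol_ppm, off_by_one):
    """Match fragments to peaks within a ppm window.

    Returns (matched fragment mask, indices of distinct matched peaks).  Each
    peak counts once toward the match count regardless of how many fragments
    hit it ("unique matching").
    """
    owner, peak = _all_hits(peak_mz, frag_mz, frag_z, tol_ppm, off_by_one)
    frag_matched = np.zeros(len(frag_mz), dtype=bool)
    frag_matched[owner] = True
    return frag_matched, np.unique(peak)


def _binomial_tail_score(k: int, n: int, p: float) -> float:
    """-log10 P(X >= k) for X ~ Binomial(n, p), underflow-safe.

    Uses the regularized incomplete beta identity P(X >= k) = I_p(k, n-k+1);
    when that underflows to 0 (overwhelming matches) the tail is summed from
    log-pmf terms instead.
    """
    if k <= 0:
        return 0.0
    sf = betainc(k, n - k + 1, p)
    if sf > 0.0:
        return float(-np.log10(sf))
    i = np.arange(k, n + 1, dtype=float)
    log_terms = (
        gammaln(n + 1.0)
        - gammaln(i + 1.0)
        - gammaln(n - i + 1.0)
        + i * np.log(p)
        + (n - i) * np.log1p(-p)
    )
    return float(-logsumexp(log_terms) / np.log(10.0))


def _score_arrays(peak_mz, frag_mz, frag_z, frag_bond, n_bonds, config):
    """Binomial-tail score of the fragment/peak match.

    Per-fragment match probability p is estimated from the spectrum's peak
    density times the tolerance window; the score is -log10 of the binomial
    survival probability of >= k distinct peak matches among N fragments.
    """
    n_frag = len(frag_mz)
    if len(peak_mz) == 0 or n_frag == 0:
        return 0.0, 0.0, 0
    frag_matched, distinct_peaks = _match_arrays(
        peak_mz, frag_mz, frag_z, config.ms2_tol_ppm, config.allow_off_by_one
    )
    k = len(distinct_peaks)
    span = max(peak_mz[-1] - peak_mz[0], 1.0)
    density = len(peak_mz) / span
    n_windows = 3 if config.allow_off_by_one else 1
    mean_window = float(np.mean(2.0 * config.ms2_tol_ppm * 1e-6 * frag_mz)) * n_windows
    p = float(np.clip(density * mean_window, 1e-9, 0.5))
    k_eff = min(k, n_frag)
    score = _binomial_tail_score(k_eff, n_frag, p)
    supported = np.unique(frag_bond[frag_matched])
    coverage = len(supported) / n_bonds if n_bonds > 0 else 0.0
    return score, coverage, k


def score_psm(
    spectrum: SpectrumRecord,
    fragments: list[TheoreticalFragment],
    config: SearchConfig = SearchConfig(),
    n_bonds: int | None = None,
) -> tuple[float, float, int]:
    """Score a spectrum against an explicit theoretical fragment list.

    Returns (score, fragment coverage, distinct matched peak count).
    """
    if not fragments:
        return 0.0, 0.0, 0
    frag_mz = np.array([f.mz for f in fragments])
    frag_z = np.array([f.charge for f in fragments], dtype=float)
    if n_bonds is None:
        n_bonds = max(max(f.index for f in fragments), 1)
    bond = np.array(
        [f.index if f.series == "b" else n_bonds + 1 - f.index for f in fragments]
    )
    return _score_arrays(spectrum.mz, frag_mz, frag_z, bond, n_bonds, config)


def _score_all_sites(peak_mz, cand: "_CandidateFragments", config: SearchConfig):
    """Score every candidate crosslink site against one peak list.

    Fragment/peak matching runs once over the site-independent fragment
    superset; per-site scores are then derived by masking the stub block to
    site-spanning fragments.
    """
    n = cand.n
    scores = np.zeros(n)
    covs = np.zeros(n)
    matched_counts = np.zeros(n, dtype=int)
    stub_matched = np.zeros(n, dtype=bool)
    mz, z, bond, is_b, ion_index, is_stub = cand.full_arrays()
    if len(peak_mz) == 0:
        return scores, covs, matched_counts, stub_matched
    owner, peak = _all_hits(peak_mz, mz, z, config.ms2_tol_ppm, config.allow_off_by_one)
    span_peaks = max(peak_mz[-1] - peak_mz[0], 1.0)
    density = len(peak_mz) / span_peaks
    n_windows = 3 if config.allow_off_by_one else 1
    window_per_mz = 2.0 * config.ms2_tol_ppm * 1e-6 * n_windows * density
    frag_matched = np.zeros(len(mz), dtype=bool)
    frag_matched[owner] = True
    for site in range(1, n + 1):
        spans = np.where(is_b, ion_index >= site, ion_index >= n - site + 1)
        sel = ~is_stub | spans
        n_frag = int(sel.sum())
        sel_hits = sel[owner]
        k = int(np.unique(peak[sel_hits]).size)
        p = float(np.clip(window_per_mz * mz[sel].mean(), 1e-9, 0.5))
        scores[site - 1] = _binomial_tail_score(min(k, n_frag), n_frag, p)
        supported = np.unique(bond[sel & frag_matched])
        covs[site - 1] = len(supported) / (n - 1) if n > 1 else 0.0
        matched_counts[site - 1] = k
        stub_matched[site - 1] = bool((sel & is_stub & frag_matched).any())
    return scores, covs, matched_counts, stub_matched


_TIE_EPS = 1e-9


def search_spectrum(
    spectrum: SpectrumRecord,
    index: CandidateIndex,
    config: SearchConfig = SearchConfig(),
    max_rank: int = 1,
) -> list[CrosslinkPSM]:
    """Search one spectrum; returns up to ``max_rank`` PSMs, best first.

    Targets and decoys compete in the same candidate pool.  Within the winning
    candidate the crosslink site is reported as undefined when the two best
    site scores tie — i.e. no stub-bearing ion discriminates between them.
    """
    if not (config.min_charge <= spectrum.charge <= config.max_charge):
        return []
    neutral = spectrum.neutral_mass()
    candidates = index.query(neutral, config.ms1_tol_ppm)
    results = []
    for peptide, adduct in candidates:
        cand = _candidate_fragments_cached(peptide, adduct, config)
        n = len(peptide.sequence)
        site_scores, site_cov, site_matched, site_stub = _score_all_sites(
            spectrum.mz, cand, config
        )
        best = int(np.argmax(site_scores))
        best_score = site_scores[best]
        ties = np.sum(site_scores >= best_score - _TIE_EPS)
        # localized only when a stub-bearing ion supports the single best site
        site: int | None = best + 1 if ties == 1 and site_stub[best] else None
        results.append(
            CrosslinkPSM(
                spectrum_id=spectrum.spectrum_id,
                peptide=peptide,
                adduct=adduct,
                site=site,
                score=float(best_score),
                is_decoy=peptide.is_decoy,
                coverage=float(site_cov[best]),
                matched_peaks=int(site_matched[best]),
            )
        )
    results.sort(
        key=lambda p: (-p.score, p.peptide.protein_id, p.peptide.sequence, p.adduct.label)
    )
    return results[:max_rank]


def run_search(
    spectra: list[SpectrumRecord],
    index: CandidateIndex,
    config: SearchConfig = SearchConfig(),
) -> list[CrosslinkPSM]:
    """Best PSM per spectrum (spectra with no candidate in window are skipped)."""
    out = []
    for spectrum in spectra:
        hits = search_spectrum(spectrum, index, config)
        if hits:
            out.append(hits[0])
    return out


def compute_fdr(psms: list[CrosslinkPSM], threshold: float = 0.01) -> FdrResult:
    """Target/decoy FDR on the score-sorted PSM list.

    PSMs are sorted by descending score (decoys first on ties — conservative);
    running FDR_i = decoys_i / max(targets_i, 1); q-values are the cumulative
    minimum of the running FDR from the bottom; the accepted set is the largest
    prefix with q <= threshold.
    """
    if not psms:
        raise ValueError("no PSMs to compute FDR on")
    order = sorted(range(len(psms)), key=lambda i: (-psms[i].score, not psms[i].is_decoy))
    ranked = [psms[i] for i in order]
    decoy = np.array([p.is_decoy for p in ranked])
    cum_decoy = np.cumsum(decoy)
    cum_target = np.cumsum(~decoy)
    running = cum_decoy / np.maximum(cum_target, 1)
    q = np.minimum.accumulate(running[::-1])[::-1]
    accepted_mask = q <= threshold
    if accepted_mask.any():
        cut = int(np.max(np.nonzero(accepted_mask)[0])) + 1
    else:
        cut = 0
    accepted = [p for p in ranked[:cut] if not p.is_decoy]
    score_threshold = ranked[cut - 1].score if cut > 0 else float("inf")
    return FdrResult(ranked, running, q, accepted, score_threshold)


def deduplicate_psms(psms: list[CrosslinkPSM]) -> list[CrosslinkSite]:
    """Collapse accepted PSMs into unique crosslink sites.

    Drops PSMs with undefined site; keeps the best score per (protein,
    absolute residue), then the best score per (peptide sequence, adduct).
    """
    defined = [p for p in psms if p.site is not None]
    by_residue: dict[tuple[str, int], CrosslinkPSM] = {}
    for p in defined:
        pos = p.peptide.start + p.site - 1
        key = (p.peptide.protein_id, pos)
        cur = by_residue.get(key)
        if cur is None or p.score > cur.score:
            by_residue[key] = p
    by_pep_rna: dict[tuple[str, str], tuple[tuple[str, int], CrosslinkPSM]] = {}
    for key, p in sorted(by_residue.items()):
        k2 = (p.peptide.sequence, p.adduct.label)
        cur = by_pep_rna.get(k2)
        if cur is None or p.score > cur[1].score:
            by_pep_rna[k2] = (key, p)
    sites = []
    for (protein, pos), p in sorted(v for v in by_pep_rna.values()):
        aa = p.peptide.sequence[p.site - 1]
        sites.append(
            CrosslinkSite(
                protein_id=protein,
                position=pos,
                amino_acid=aa,
                adduct_label=p.adduct.label,
                score=p.score,
                peptide_sequence=p.peptide.sequence,
                missed_cleavages=p.peptide.missed_cleavages,
            )
        )
    return sites
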