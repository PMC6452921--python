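"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators: random proteomes (FASTA-ready), MS2 spectra of RNA-conjugated
tryptic peptides (stub fragmentation, ppm-scale mass error, noise peaks), and
SILAC peptide intensity tables with intensity-dependent (left-censored)
missingness and a planted set of UV-enriched proteins.  Every generator is a
pure function of its configuration and seed, and returns a truth record
sufficient to score the downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import PROTON_MASS, RnaAdduct
from .digest import PeptideCandidate, ProteinRecord
from .search import SearchConfig, SpectrumRecord, _CandidateFragments

__all__ = [
    "SpectrumSimConfig",
    "SilacSimConfig",
    "generate_proteome",
    "simulate_conjugate_spectrum",
    "simulate_silac_table",
]

_AMINO_ACIDS = "ACDEFGHILMNPQSTVWY"  # the 18 non-K/R residues


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Conditions for simulated conjugate MS2 spectra.

    ``detection_prob`` is the chance each theoretical fragment produces a peak;
    ``ppm_error`` the Gaussian m/z error scale; noise peaks are uniform over
    ``noise_mz_range`` with exponential intensities.
    """

    detection_prob: float = 0.7
    n_noise_peaks: int = 50
    noise_mz_range: tuple[float, float] = (100.0, 1800.0)
    ppm_error: float = 5.0
    intensity_scale: float = 1000.0
    charge_range: tuple[int, int] = (2, 4)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.detection_prob <= 1):
            raise ValueError("detection_prob must be in (0, 1]")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be >= 0")


@dataclass(frozen=True)
class SilacSimConfig:
    """Conditions for simulated SILAC peptide tables.

    Intensities are log-normal (log2 scale); true binders get the planted log2
    effect added to the irradiated channel; cells go missing with a logistic
    probability in log2 intensity (midpoint/slope), so low-abundance signals
    preferentially drop out (left censoring, missing-not-at-random).
    """

    n_proteins: int = 500
    mean_peptides_per_protein: float = 4.0
    orientations: tuple[str, ...] = ("forward", "forward", "reverse")
    binder_fraction: float = 0.1
    binder_log2_effect: float = 2.0
    base_log2_intensity: float = 26.0
    protein_log2_sd: float = 2.0
    peptide_log2_sd: float = 1.0
    channel_noise_sd: float = 0.25
    censor_midpoint: float = 23.0
    censor_slope: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.binder_fraction <= 1):
            raise ValueError("binder_fraction must be in [0, 1]")
        if len(self.orientations) < 2:
            raise ValueError("at least 2 experiments required")


def generate_proteome(
    n_proteins: int,
    mean_length: float = 300.0,
    seed: int = 0,
    kr_fraction: float = 0.10,
) -> list[ProteinRecord]:
    """Random protein sequences with a controlled K+R frequency.

    Lengths are geometric-ish (gamma) around ``mean_length`` with a floor of
    30 residues; K and R each occur at kr_fraction/2 so tryptic peptides have
    realistic lengths (~1/kr_fraction residues on average).
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_proteins):
        length = max(30, int(rng.gamma(shape=4.0, scale=mean_length / 4.0)))
        is_kr = rng.random(length) < kr_fraction
        kr = rng.choice(list("KR"), size=length)
        other = rng.choice(list(_AMINO_ACIDS), size=length)
        seq = "".join(np.where(is_kr, kr, other))
        records.append(ProteinRecord(f"SYN{i:04d}", seq))
    return records


def simulate_conjugate_spectrum(
    peptide: PeptideCandidate,
    adduct: RnaAdduct,
    site: int,
    config: SpectrumSimConfig = SpectrumSimConfig(),
    rng: np.random.Generator | None = None,
    search_config: SearchConfig = SearchConfig(),
    spectrum_id: str | None = None,
) -> tuple[SpectrumRecord, dict]:
    """Simulate one MS2 spectrum of a peptide crosslinked to an RNA adduct.

    Theoretical fragments (same chemistry as the search) are sampled at the
    detection probability, perturbed by Gaussian ppm error, and merged with
    uniform noise peaks.  The truth record stores (peptide, adduct, site).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cand = _CandidateFragments(peptide, adduct, search_config)
    mz, z, bond, stub = cand.site_arrays(site)
    mz = np.unique(mz)
    keep = rng.random(len(mz)) < config.detection_prob
    frag_mz = mz[keep]
    frag_mz = frag_mz * (1.0 + rng.normal(0.0, config.ppm_error * 1e-6, len(frag_mz)))
    frag_int = rng.exponential(config.intensity_scale, len(frag_mz))
    lo, hi = config.noise_mz_range
    noise_mz = rng.uniform(lo, hi, config.n_noise_peaks)
    noise_int = rng.exponential(config.intensity_scale / 5.0, config.n_noise_peaks)
    all_mz = np.concatenate([frag_mz, noise_mz])
    all_int = np.concatenate([frag_int, noise_int])
    charge = int(rng.integers(config.charge_range[0], config.charge_range[1] + 1))
    neutral = peptide.mass + adduct.precursor_mass
    precursor_mz = (neutral + charge * PROTON_MASS) / charge
    sid = spectrum_id or f"sim|{peptide.sequence}|{adduct.label}|{site}"
    spectrum = SpectrumRecord(sid, precursor_mz, charge, all_mz, all_int)
    truth = {
        "spectrum_id": sid,
        "peptide": peptide.sequence,
        "protein_id": peptide.protein_id,
        "adduct_label": adduct.label,
        "site": site,
    }
    return spectrum, truth


def simulate_noise_spectrum(
    config: SpectrumSimConfig,
    rng: np.random.Generator,
    precursor_mz: float,
    charge: int,
    n_peaks: int = 120,
    spectrum_id: str = "noise",
) -> SpectrumRecord:
    """A pure-noise spectrum at a given precursor (for FDR calibration runs)."""
    lo, hi = config.noise_mz_range
    mz = rng.uniform(lo, hi, n_peaks)
    intensity = rng.exponential(config.intensity_scale / 5.0, n_peaks)
    return SpectrumRecord(spectrum_id, precursor_mz, charge, mz, intensity)


def simulate_silac_table(config: SilacSimConfig = SilacSimConfig()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a SILAC peptide evidence table plus its truth record.

    Returns (table, truth).  The table follows the peptide-evidence dialect:
    Sequence, Leading razor protein, Reverse, Potential contaminant and
    per-experiment "Intensity H expN" / "Intensity L expN" columns.  Truth
    lists each protein's binder flag and planted log2 effect.
    """
    rng = np.random.default_rng(config.seed)
    n_exp = len(config.orientations)
    exp_names = [f"exp{i + 1}" for i in range(n_exp)]
    is_binder = rng.random(config.n_proteins) < config.binder_fraction
    effects = np.where(is_binder, config.binder_log2_effect, 0.0)
    rows = []
    pep_counter = 0
    for i in range(config.n_proteins):
        protein = f"SYNP{i:04d}"
        n_pep = 1 + rng.poisson(config.mean_peptides_per_protein - 1.0)
        protein_level = rng.normal(config.base_log2_intensity, config.protein_log2_sd)
        for _ in range(n_pep):
            pep_level = protein_level + rng.normal(0.0, config.peptide_log2_sd)
            row = {
                "Sequence": f"PEP{pep_counter:06d}",
                "Leading razor protein": protein,
                "Reverse": "",
                "Potential contaminant": "",
            }
            pep_counter += 1
            for exp, orientation in zip(exp_names, config.orientations):
                minus_uv = pep_level + rng.normal(0.0, config.channel_noise_sd)
                plus_uv = pep_level + effects[i] + rng.normal(0.0, config.channel_noise_sd)
                if orientation == "forward":  # light cells irradiated
                    log_l, log_h = plus_uv, minus_uv
                else:
                    log_l, log_h = minus_uv, plus_uv
                for label, logint in (("H", log_h), ("L", log_l)):
                    if np.isneginf(config.censor_midpoint):
                        p_missing = 0.0  # censoring disabled
                    else:
                        p_missing = 1.0 / (
                            1.0 + np.exp(config.censor_slope * (logint - config.censor_midpoint))
                        )
                    value = 0.0 if rng.random() < p_missing else 2.0 ** logint
                    row[f"Intensity {label} {exp}"] = value
            rows.append(row)
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "protein": [f"SYNP{i:04d}" for i in range(config.n_proteins)],
            "is_binder": is_binder,
            "log2_effect": effects,
        }
    )
    return table, truth
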