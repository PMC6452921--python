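"""Ground-truthed benchmark experiments for the pipeline's statistical claims.

Each function builds its own synthetic inputs (via :mod:`trappkit.simulate`),
runs the relevant pipeline stage, and measures recovery/calibration against
the planted truth.  They are used both by the validation test suite and by
``scripts/acceptance.py``; every function is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chem import PROTON_MASS, enumerate_targeted_adducts, retention_fragment_set
from .digest import digest_database, generate_decoys
from .search import SearchConfig, build_candidate_index, compute_fdr, search_spectrum
from .silac import ImputationParams, moderated_test, run_enrichment
from .simulate import (
    SilacSimConfig,
    SpectrumSimConfig,
    generate_proteome,
    simulate_conjugate_spectrum,
    simulate_noise_spectrum,
    simulate_silac_table,
)
from .sitestats import ColocalizationParams, phosphosite_colocalization
from .search import CrosslinkSite

__all__ = [
    "retained_mass_table",
    "planted_recovery",
    "fdr_calibration",
    "silac_null_calibration",
    "silac_power",
    "coloc_null_calibration",
    "coloc_planted_power",
]


def retained_mass_table() -> dict[str, float]:
    """The eight 4tU-derived retained-fragment masses, recomputed from formulas."""
    return {f.label: f.mass for f in retention_fragment_set()}


def _search_setup(n_proteins: int, proteome_seed: int):
    proteome = generate_proteome(n_proteins, mean_length=150, seed=proteome_seed)
    database = proteome + generate_decoys(proteome)
    peptides = digest_database(database)
    adducts = enumerate_targeted_adducts(max_len=1, alphabet=("4tU",))
    index = build_candidate_index(peptides, adducts)
    targets = [p for p in peptides if not p.is_decoy and 7 <= len(p.sequence) <= 18]
    return index, targets, adducts


def planted_recovery(n_spectra: int = 200, n_proteins: int = 100, seed: int = 0) -> float:
    """Fraction of noiseless conjugate spectra identified exactly at rank 1.

    Noiseless means every theoretical fragment present at its exact m/z
    (detection probability 1, zero ppm error, no noise peaks); exact means the
    planted peptide, adduct and crosslink site are all recovered, from a
    target+decoy database over the full proteome.
    """
    index, targets, adducts = _search_setup(n_proteins, proteome_seed=seed + 1)
    rng = np.random.default_rng(seed)
    sim = SpectrumSimConfig(detection_prob=1.0, n_noise_peaks=0, ppm_error=0.0)
    config = SearchConfig()
    hits = 0
    for _ in range(n_spectra):
        pep = targets[rng.integers(len(targets))]
        adduct = adducts[rng.integers(len(adducts))]
        site = int(rng.integers(1, len(pep.sequence) + 1))
        spectrum, _ = simulate_conjugate_spectrum(pep, adduct, site, sim, rng=rng)
        found = search_spectrum(spectrum, index, config)
        if (
            found
            and not found[0].is_decoy
            and found[0].peptide.sequence == pep.sequence
            and found[0].adduct.label == adduct.label
            and found[0].site == site
        ):
            hits += 1
    return hits / n_spectra


def fdr_calibration(
    n_seeds: int = 20,
    n_planted: int = 150,
    n_noise: int = 100,
    n_proteins: int = 50,
    threshold: float = 0.01,
    seed: int = 0,
) -> dict[str, float]:
    """Realized false discovery proportion of the accepted set, pooled over seeds.

    Each seeded run searches a mix of realistic planted spectra (detection
    probability 0.6, 5 ppm error, 40 noise peaks) and pure-noise spectra whose
    precursors sit on random candidate masses, then accepts PSMs at the
    decoy-estimated ``threshold``.  A discovery is false when its spectrum was
    noise or its peptide differs from the planted one.
    """
    index, targets, adducts = _search_setup(n_proteins, proteome_seed=seed + 11)
    config = SearchConfig()
    sim = SpectrumSimConfig(detection_prob=0.6, n_noise_peaks=40, ppm_error=5.0)
    total_accepted = 0
    total_false = 0
    for run in range(n_seeds):
        rng = np.random.default_rng(seed * 1000 + run)
        psms = []
        truth = {}
        for i in range(n_planted):
            pep = targets[rng.integers(len(targets))]
            adduct = adducts[rng.integers(len(adducts))]
            site = int(rng.integers(1, len(pep.sequence) + 1))
            spectrum, _ = simulate_conjugate_spectrum(
                pep, adduct, site, sim, rng=rng, spectrum_id=f"planted{i}"
            )
            truth[f"planted{i}"] = pep.sequence
            found = search_spectrum(spectrum, index, config)
            if found:
                psms.append(found[0])
        for i in range(n_noise):
            mass = index.masses[rng.integers(len(index.masses))]
            z = int(rng.integers(2, 5))
            spectrum = simulate_noise_spectrum(
                sim, rng, (mass + z * PROTON_MASS) / z, z, spectrum_id=f"noise{i}"
            )
            found = search_spectrum(spectrum, index, config)
            if found:
                psms.append(found[0])
        result = compute_fdr(psms, threshold)
        total_accepted += len(result.accepted)
        total_false += sum(
            1
            for p in result.accepted
            if p.spectrum_id.startswith("noise")
            or truth[p.spectrum_id] != p.peptide.sequence
        )
    return {
        "realized_fdp": total_false / max(total_accepted, 1),
        "n_accepted": total_accepted,
        "n_false": total_false,
    }


def silac_null_calibration(
    n_proteins: int = 5000, n_experiments: int = 3, seed: int = 0
) -> dict[str, float]:
    """Type-I behavior of the moderated test on null protein log2 ratios.

    Ratios are Normal(0, sigma^2) with protein-specific sigma^2 drawn from a
    scaled inverse-chi-square (d0=4, s0=0.3), the hierarchical model the
    moderated test assumes; raw p-values should then be uniform.
    """
    rng = np.random.default_rng(seed)
    d0_true, s0_true = 4.0, 0.3
    sigma_sq = d0_true * s0_true**2 / rng.chisquare(d0_true, n_proteins)
    ratios = rng.normal(0.0, np.sqrt(sigma_sq)[:, None], (n_proteins, n_experiments))
    table = pd.DataFrame(ratios, columns=[f"exp{i + 1}" for i in range(n_experiments)])
    result = moderated_test(table)
    return {
        "p05_fraction": float((result["p_value"] < 0.05).mean()),
        "n_bh_enriched": int(result["enriched"].sum()),
        "n_tested": int(result["p_value"].notna().sum()),
    }


def silac_power(
    n_seeds: int = 10, n_proteins: int = 400, seed: int = 0
) -> dict[str, float]:
    """Sensitivity and realized FDR for planted 4-fold binders.

    Full-pipeline runs (generator -> imputation -> ratios -> moderated test)
    with the generator defaults: 10% binders at log2 effect 2, three SILAC
    experiments (two forward, one reverse), left-censored missingness.
    """
    design = {"exp1": "forward", "exp2": "forward", "exp3": "reverse"}
    tp = fp = fn = 0
    for run in range(n_seeds):
        cfg = SilacSimConfig(n_proteins=n_proteins, seed=seed * 1000 + run)
        table, truth = simulate_silac_table(cfg)
        result = run_enrichment(table, design, ImputationParams(seed=seed * 1000 + run))
        truth = truth.set_index("protein")
        binders = set(truth.index[truth["is_binder"]]) & set(result.index)
        called = set(result.index[result["enriched"]])
        tp += len(called & binders)
        fp += len(called - binders)
        fn += len(binders - called)
    return {
        "sensitivity": tp / max(tp + fn, 1),
        "realized_fdr": fp / max(tp + fp, 1),
        "n_called": tp + fp,
        "n_binders": tp + fn,
    }


def _coloc_null_dataset(rng, n_proteins=30, length=400, n_phospho=3, n_sites=2):
    sequences = {f"P{i}": "A" * length for i in range(n_proteins)}
    positions = np.arange(1, length + 1)
    phospho = {
        f"P{i}": [int(x) for x in rng.choice(positions, n_phospho, replace=False)]
        for i in range(n_proteins)
    }
    sites = [
        CrosslinkSite(f"P{i}", int(p), "A", "4tU", 10.0)
        for i in range(n_proteins)
        for p in rng.choice(positions, n_sites, replace=False)
    ]
    return sites, phospho, sequences


def coloc_null_calibration(n_datasets: int = 500, seed: int = 0) -> dict[str, float]:
    """Rejection rate of the shuffle chi-square test on uniform null datasets."""
    rejections = 0
    for run in range(n_datasets):
        rng = np.random.default_rng(seed * 10000 + run)
        sites, phospho, sequences = _coloc_null_dataset(rng)
        report = phosphosite_colocalization(
            sites, phospho, sequences, ColocalizationParams(seed=seed * 10000 + run + 1)
        )
        rejections += report.p_value < 0.05
    return {"type1_rate": rejections / n_datasets, "n_datasets": n_datasets}


def coloc_planted_power(n_datasets: int = 100, seed: int = 0) -> dict[str, float]:
    """Detection rate when crosslink sites are planted near phosphosites."""
    detected = 0
    for run in range(n_datasets):
        rng = np.random.default_rng(seed * 10000 + run)
        _, phospho, sequences = _coloc_null_dataset(rng)
        sites = [
            CrosslinkSite(protein, int(np.clip(p + rng.integers(-5, 6), 1, 400)),
                          "A", "4tU", 10.0)
            for protein, positions in phospho.items()
            for p in positions[:2]
        ]
        report = phosphosite_colocalization(
            sites, phospho, sequences, ColocalizationParams(seed=seed * 10000 + run + 1)
        )
        detected += report.p_value < 0.05
    return {"power": detected / n_datasets, "n_datasets": n_datasets}
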