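"""Post-identification crosslink-site statistics.

Amino-acid crosslink efficiency (site frequency relative to the residue's
frequency in the crosslinked peptide pool), missed-cleavage tabulation,
a permutation (shuffle) test for colocalization of crosslink sites with
phosphosites, and abundance-binned enrichment ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .search import CrosslinkSite

__all__ = [
    "ColocalizationParams",
    "ColocalizationReport",
    "crosslink_efficiency",
    "missed_cleavage_stats",
    "phosphosite_colocalization",
    "abundance_bin_enrichment",
]


@dataclass(frozen=True)
class ColocalizationParams:
    """Window (residues) around a phosphosite, number of shuffles, seed.

    ``restrict_sty`` limits shuffled phosphosite placements to S/T/Y residues;
    by default any residue position is allowed.
    """

    window: int = 20
    n_shuffles: int = 100
    seed: int = 0
    restrict_sty: bool = False

    def __post_init__(self):
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.n_shuffles < 1:
            raise ValueError("need at least one shuffle")


@dataclass(frozen=True)
class ColocalizationReport:
    observed_inside: int
    observed_outside: int
    expected_inside: float
    expected_outside: float
    chi2_statistic: float
    p_value: float
    n_shuffles: int


def crosslink_efficiency(
    sites: list[CrosslinkSite],
    peptides: list[str],
) -> pd.DataFrame:
    """Per-amino-acid crosslink efficiency.

    Efficiency is the frequency of the amino acid at crosslink sites divided
    by its frequency across all crosslinked peptide sequences (residues
    counted with multiplicity).  Amino acids absent from the peptide pool are
    omitted.
    """
    if not sites or not peptides:
        raise ValueError("sites and peptides must be non-empty")
    pool = "".join(peptides)
    pool_counts = pd.Series(list(pool)).value_counts()
    pool_freq = pool_counts / pool_counts.sum()
    site_counts = pd.Series([s.amino_acid for s in sites]).value_counts()
    site_freq = (site_counts / site_counts.sum()).reindex(pool_freq.index, fill_value=0.0)
    out = pd.DataFrame(
        {
            "site_frequency": site_freq,
            "pool_frequency": pool_freq,
            "efficiency": site_freq / pool_freq,
        }
    )
    out.index.name = "amino_acid"
    return out.sort_index()


def missed_cleavage_stats(
    entries: list[tuple[int, str]],
) -> dict[str, float]:
    """Fractions of crosslinked peptides with 1-2 missed cleavages.

    ``entries`` are (missed cleavage count, crosslinked amino acid) pairs.
    Returns the overall fraction with >= 1 missed cleavage and the same
    fraction among peptides whose reported crosslink site is K or R.
    """
    if not entries:
        return {"fraction_missed": 0.0, "fraction_missed_kr": 0.0, "n": 0, "n_kr": 0}
    mc = np.array([e[0] for e in entries])
    kr = np.array([e[1] in "KR" for e in entries])
    n_kr = int(kr.sum())
    return {
        "fraction_missed": float((mc >= 1).mean()),
        "fraction_missed_kr": float((mc[kr] >= 1).mean()) if n_kr else 0.0,
        "n": len(entries),
        "n_kr": n_kr,
    }


def _count_inside(site_pos: np.ndarray, phospho_pos: np.ndarray, window: int) -> int:
    if len(site_pos) == 0 or len(phospho_pos) == 0:
        return 0
    d = np.abs(site_pos[:, None] - phospho_pos[None, :])
    return int((d.min(axis=1) <= window).sum())


def _draw_positions(
    rng: np.random.Generator, k: int, allowed: np.ndarray, n_shuffles: int
) -> np.ndarray:
    """(n_shuffles, k) positions drawn without replacement from ``allowed``.

    Rejection sampling on duplicate rows; falls back to per-row permutation
    draws when k is a large fraction of the allowed positions.
    """
    m = len(allowed)
    if k > m:
        raise ValueError("more phosphosites than allowed positions")
    if k > m // 2:
        return np.array([rng.choice(allowed, size=k, replace=False) for _ in range(n_shuffles)])
    draws = rng.integers(0, m, size=(n_shuffles, k))
    for _ in range(100):
        sorted_rows = np.sort(draws, axis=1)
        bad = (np.diff(sorted_rows, axis=1) == 0).any(axis=1) if k > 1 else np.zeros(n_shuffles, bool)
        if not bad.any():
            break
        draws[bad] = rng.integers(0, m, size=(int(bad.sum()), k))
    return allowed[draws]


def phosphosite_colocalization(
    sites: list[CrosslinkSite],
    phospho: dict[str, list[int]],
    protein_sequences: dict[str, str],
    params: ColocalizationParams = ColocalizationParams(),
) -> ColocalizationReport:
    """Shuffle test for crosslink/phosphosite colocalization.

    Counts crosslink sites within ``window`` residues of a phosphosite on the
    same protein (inside) versus outside.  Expected counts come from
    ``n_shuffles`` random redraws of each protein's phosphosite positions
    (count per protein preserved, uniform without replacement over the
    protein's residues); the observed 2-category split is compared to the
    averaged expected split with a 1-df chi-square goodness-of-fit test.
    """
    if not any(phospho.values()):
        raise ValueError("no phosphosites provided")
    rng = np.random.default_rng(params.seed)
    by_protein: dict[str, list[int]] = {}
    for s in sites:
        if s.protein_id not in protein_sequences:
            raise ValueError(f"no sequence for protein {s.protein_id}")
        by_protein.setdefault(s.protein_id, []).append(s.position)
    total_sites = len(sites)
    observed_inside = 0
    shuffle_inside = np.zeros(params.n_shuffles)
    for protein, positions in sorted(by_protein.items()):
        site_pos = np.array(positions)
        ppos = np.array(sorted(phospho.get(protein, [])))
        seq = protein_sequences[protein]
        length = len(seq)
        if len(ppos):
            if (ppos < 1).any() or (ppos > length).any():
                raise ValueError(f"phosphosite out of range for {protein}")
            observed_inside += _count_inside(site_pos, ppos, params.window)
            if params.restrict_sty:
                allowed = np.array([i + 1 for i, aa in enumerate(seq) if aa in "STY"])
            else:
                allowed = np.arange(1, length + 1)
            draws = _draw_positions(rng, len(ppos), allowed, params.n_shuffles)
            d = np.abs(site_pos[None, :, None] - draws[:, None, :])
            shuffle_inside += (d.min(axis=2) <= params.window).sum(axis=1)
    observed_outside = total_sites - observed_inside
    expected_inside = float(shuffle_inside.mean())
    expected_outside = total_sites - expected_inside
    if expected_inside <= 0 or expected_outside <= 0:
        raise ValueError(
            "a category has zero expected count; increase shuffles or pool categories"
        )
    stat = (observed_inside - expected_inside) ** 2 / expected_inside + (
        observed_outside - expected_outside
    ) ** 2 / expected_outside
    p = float(chi2.sf(stat, df=1))
    return ColocalizationReport(
        observed_inside=observed_inside,
        observed_outside=observed_outside,
        expected_inside=expected_inside,
        expected_outside=expected_outside,
        chi2_statistic=float(stat),
        p_value=p,
        n_shuffles=params.n_shuffles,
    )


def abundance_bin_enrichment(
    enriched_flags: pd.Series,
    abundances: pd.Series,
    exclude: set[str] | None = None,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Enriched/detected ratio across abundance bins.

    Proteins (after removing ``exclude``) are sorted by abundance and split
    into ``n_bins`` equal-count bins (remainder spread over the top bins);
    each bin reports its median abundance and the ratio of enriched proteins
    to all detected proteins in the bin.
    """
    proteins = enriched_flags.index
    if exclude:
        proteins = proteins.difference(pd.Index(sorted(exclude)))
    missing = proteins.difference(abundances.index)
    if len(missing):
        raise ValueError(f"no abundance for proteins: {list(missing[:5])}")
    n = len(proteins)
    if n < n_bins:
        raise ValueError(f"fewer proteins ({n}) than bins ({n_bins})")
    order = abundances.loc[proteins].sort_values(kind="stable").index
    base = n // n_bins
    remainder = n % n_bins
    sizes = [base + (1 if i >= n_bins - remainder else 0) for i in range(n_bins)]
    rows = []
    start = 0
    for i, size in enumerate(sizes):
        members = order[start : start + size]
        start += size
        flags = enriched_flags.loc[members].astype(bool)
        rows.append(
            {
                "bin": i + 1,
                "n_proteins": size,
                "median_abundance": float(abundances.loc[members].median()),
                "n_enriched": int(flags.sum()),
                "enriched_ratio": float(flags.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("bin")
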