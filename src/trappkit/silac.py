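"""SILAC UV-enrichment quantification.

Quantifies RNA-associated protein enrichment from heavy/light peptide
intensities: UV-irradiated and control cultures are mixed per experiment, so
the +UV/-UV ratio of each peptide reads out UV-dependent recovery.  The
pipeline filters contaminant/decoy rows, imputes left-censored missing
intensities, forms per-peptide ratios oriented so the numerator is always the
irradiated channel, aggregates to proteins by the median over peptides
(leading razor protein), and tests the per-protein log2 ratios against zero
with an empirical-Bayes moderated one-sample t-test and Benjamini-Hochberg
adjustment.  The same machinery supports a condition-vs-condition differential
mode (e.g. +/- sorbic acid stress), optionally restricted to a prior set of
RNA-interacting proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ImputationParams",
    "ModeratedTestHyper",
    "REQUIRED_COLUMNS",
    "filter_rows",
    "experiment_names",
    "impute_missing",
    "peptide_ratios",
    "aggregate_protein_ratios",
    "filter_proteins",
    "estimate_variance_prior",
    "moderated_test",
    "run_enrichment",
    "differential_mode",
]

REQUIRED_COLUMNS = ["Sequence", "Leading razor protein", "Reverse", "Potential contaminant"]

PRESETS = {
    "par-trapp": {"q": 0.1, "tune_sigma": 0.01},
    "trapp-yeast": {"q": 0.1, "tune_sigma": 0.0035},
}


@dataclass(frozen=True)
class ImputationParams:
    """Left-censored imputation: draws centered at the q-quantile of each
    channel's observed log2 intensities, spread tune_sigma x the median of
    per-channel observed standard deviations."""

    q: float = 0.1
    tune_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.q < 1):
            raise ValueError("q must be in (0, 1)")
        if self.tune_sigma <= 0:
            raise ValueError("tune_sigma must be positive")


@dataclass(frozen=True)
class ModeratedTestHyper:
    """Empirical-Bayes variance prior: d0 prior df, s0_sq prior variance."""

    d0: float
    s0_sq: float


def _check_columns(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peptide table is missing required columns: {missing}")


def experiment_names(table: pd.DataFrame) -> list[str]:
    """Experiment identifiers from 'Intensity H <exp>' / 'Intensity L <exp>' columns."""
    h = {c[len("Intensity H "):] for c in table.columns if c.startswith("Intensity H ")}
    l = {c[len("Intensity L "):] for c in table.columns if c.startswith("Intensity L ")}
    if h != l:
        raise ValueError(f"unpaired intensity columns: H={sorted(h)} L={sorted(l)}")
    if not h:
        raise ValueError("no intensity columns found")
    return sorted(h)


def filter_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Remove contaminant and decoy (reverse) peptide rows, preserving order."""
    _check_columns(table)
    rev = table["Reverse"].fillna("").astype(str).str.strip() == "+"
    con = table["Potential contaminant"].fillna("").astype(str).str.strip() == "+"
    return table.loc[~(rev | con)].copy()


def _intensity_col(label: str, exp: str) -> str:
    return f"Intensity {label} {exp}"


def impute_missing(
    table: pd.DataFrame,
    params: ImputationParams = ImputationParams(),
    design: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute left-censored missing intensities channel by channel.

    Missing cells (NaN or 0) in each channel (experiment x label) are drawn
    from a Gaussian on the log2 scale centered at that channel's q-quantile of
    observed log2 intensities, with standard deviation tune_sigma times the
    median of per-channel observed standard deviations, then back-transformed.
    Peptides missing both the heavy and light channel of an experiment are
    reset to missing afterwards (no evidence the peptide was present at all in
    that replicate).  Returns (imputed table, boolean mask of imputed cells).
    """
    exps = experiment_names(table)
    out = table.copy()
    rng = np.random.default_rng(params.seed)
    channels = [(exp, label) for exp in exps for label in ("H", "L")]
    logs = {}
    for exp, label in channels:
        col = _intensity_col(label, exp)
        vals = pd.to_numeric(out[col], errors="coerce").replace(0.0, np.nan)
        out[col] = vals
        observed = np.log2(vals.dropna())
        if observed.empty:
            raise ValueError(f"channel {col!r} has no observed intensities")
        logs[(exp, label)] = observed
    stds = [v.std(ddof=1) for v in logs.values() if len(v) >= 2]
    sigma = params.tune_sigma * float(np.median(stds)) if stds else 0.0
    both_missing = {
        exp: out[_intensity_col("H", exp)].isna() & out[_intensity_col("L", exp)].isna()
        for exp in exps
    }
    mask = pd.DataFrame(False, index=out.index, columns=[_intensity_col(l, e) for e, l in channels])
    for exp, label in channels:
        col = _intensity_col(label, exp)
        center = float(logs[(exp, label)].quantile(params.q))
        miss = out[col].isna()
        n_miss = int(miss.sum())
        if n_miss:
            draws = rng.normal(center, sigma, n_miss)
            out.loc[miss, col] = 2.0 ** draws
            mask.loc[miss, col] = True
    for exp in exps:
        both = both_missing[exp]
        for label in ("H", "L"):
            col = _intensity_col(label, exp)
            out.loc[both, col] = np.nan
            mask.loc[both, col] = False
    return out, mask


def peptide_ratios(table: pd.DataFrame, design: dict[str, str]) -> pd.DataFrame:
    """Per-peptide +UV/-UV ratios, one column per experiment.

    Forward experiments irradiated the light-labelled culture, so the ratio is
    light/heavy; reverse experiments the opposite.  Undefined (either channel
    missing, or zero denominator) ratios are NaN.
    """
    exps = experiment_names(table)
    unknown = [e for e in exps if e not in design]
    if unknown:
        raise ValueError(f"experiments missing from design: {unknown}")
    ratios = {}
    for exp in exps:
        h = pd.to_numeric(table[_intensity_col("H", exp)], errors="coerce")
        l = pd.to_numeric(table[_intensity_col("L", exp)], errors="coerce")
        orientation = design[exp]
        if orientation == "forward":
            num, den = l, h
        elif orientation == "reverse":
            num, den = h, l
        else:
            raise ValueError(f"unknown orientation {orientation!r} for experiment {exp}")
        r = num / den
        ratios[exp] = r.where(np.isfinite(r))
    out = pd.DataFrame(ratios, index=table.index)
    out.insert(0, "Leading razor protein", table["Leading razor protein"])
    return out


def aggregate_protein_ratios(ratio_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-of-peptides protein ratios, log2 transformed.

    Returns (log2 ratio table, peptide count table), both indexed by protein
    with one column per experiment.
    """
    exps = [c for c in ratio_table.columns if c != "Leading razor protein"]
    grouped = ratio_table.groupby("Leading razor protein")
    med = grouped[exps].median()
    counts = grouped[exps].count()
    log2 = np.log2(med.where(med > 0))
    return log2, counts


def filter_proteins(
    log2_ratios: pd.DataFrame,
    counts: pd.DataFrame,
    min_peptides: int = 2,
    min_experiments: int = 2,
) -> pd.DataFrame:
    """Keep proteins quantified with >= min_peptides peptides in >= min_experiments experiments."""
    keep = (counts >= min_peptides).sum(axis=1) >= min_experiments
    return log2_ratios.loc[keep]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y (Newton iteration on 1/trigamma)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_variance_prior(variances: np.ndarray, dfs: np.ndarray) -> ModeratedTestHyper:
    """Moment-match a scaled inverse-chi-square prior to observed sample variances.

    Works on log variances: E[log s^2] and Var[log s^2] under the hierarchical
    model involve digamma/trigamma terms in the residual df and the prior df
    d0; matching the empirical mean and variance yields (d0, s0_sq).  An
    infinite d0 (no excess spread beyond chi-square sampling noise) is
    represented by d0 = inf.
    """
    ok = np.isfinite(variances) & (variances > 0) & (dfs > 0)
    v = variances[ok]
    d = dfs[ok]
    if len(v) < 2:
        # degenerate input (all-zero or a single variance): no spread
        # information to moderate with, fall back to the ordinary t-test
        s0 = float(v[0]) if len(v) == 1 else 0.0
        return ModeratedTestHyper(d0=0.0, s0_sq=s0)
    z = np.log(v)
    e = z - polygamma(0, d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(np.mean(polygamma(1, d / 2.0)))
    if excess <= 0:
        return ModeratedTestHyper(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + polygamma(0, half_d0) - np.log(half_d0)))
    return ModeratedTestHyper(d0=d0, s0_sq=s0_sq)


def moderated_test(
    log2_ratios: pd.DataFrame,
    counts: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sample empirical-Bayes moderated t-test of log2 ratios against 0.

    Per protein with n >= 2 defined ratios: the sample variance s^2 (df =
    n - 1) is shrunk toward the prior, s~^2 = (d0 s0^2 + df s^2)/(d0 + df);
    t = mean / (s~ / sqrt(n)) on d0 + df degrees of freedom; two-sided p,
    Benjamini-Hochberg adjusted across all tested proteins; the enriched flag
    is adjusted p < alpha together with a positive fold-change.  Proteins with
    fewer than 2 ratios are reported untested (NaN statistics).
    """
    values = log2_ratios.to_numpy(dtype=float)
    n = np.isfinite(values).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(np.isfinite(values), values, np.nan), axis=1)
        var = np.nanvar(np.where(np.isfinite(values), values, np.nan), axis=1, ddof=1)
    testable = n >= 2
    dfs = (n - 1).astype(float)
    hyper = estimate_variance_prior(var[testable], dfs[testable])
    t_stat = np.full(len(values), np.nan)
    p_raw = np.full(len(values), np.nan)
    df_total = np.full(len(values), np.nan)
    if np.isinf(hyper.d0):
        s2_post = np.full(len(values), hyper.s0_sq)
        df_post = np.full(len(values), np.inf)
    else:
        s2_post = (hyper.d0 * hyper.s0_sq + dfs * var) / (hyper.d0 + dfs)
        df_post = hyper.d0 + dfs
    idx = np.where(testable)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat[idx] = mean[idx] / np.sqrt(s2_post[idx] / n[idx])
    df_total[idx] = df_post[idx]
    finite_df = np.where(np.isinf(df_post[idx]), 1e12, df_post[idx])
    p_raw[idx] = 2.0 * t_dist.sf(np.abs(t_stat[idx]), finite_df)
    p_adj = np.full(len(values), np.nan)
    if len(idx):
        p_adj[idx] = multipletests(p_raw[idx], method="fdr_bh")[1]
    result = pd.DataFrame(
        {
            "mean_log2_ratio": mean,
            "n_experiments": n,
            "t": t_stat,
            "df": df_total,
            "p_value": p_raw,
            "p_adjusted": p_adj,
            "fold_change": 2.0 ** mean,
        },
        index=log2_ratios.index,
    )
    result["enriched"] = (result["p_adjusted"] < alpha) & (result["mean_log2_ratio"] > 0)
    if counts is not None:
        for exp in counts.columns:
            result[f"n_peptides_{exp}"] = counts[exp]
    result.attrs["prior_d0"] = hyper.d0
    result.attrs["prior_s0_sq"] = hyper.s0_sq
    return result


def run_enrichment(
    table: pd.DataFrame,
    design: dict[str, str],
    params: ImputationParams = ImputationParams(),
    min_peptides: int = 2,
    min_experiments: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """The full peptide-table-to-protein-results pipeline."""
    filtered = filter_rows(table)
    imputed, _ = impute_missing(filtered, params, design)
    ratios = peptide_ratios(imputed, design)
    log2, counts = aggregate_protein_ratios(ratios)
    kept = filter_proteins(log2, counts, min_peptides, min_experiments)
    return moderated_test(kept, counts.loc[kept.index], alpha)


def differential_mode(
    table: pd.DataFrame,
    design: dict[str, str],
    restrict_to: set[str] | None = None,
    params: ImputationParams = ImputationParams(),
    min_peptides: int = 2,
    min_experiments: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Condition-vs-condition differential mode (e.g. +stress/-stress ratios).

    Same machinery as the UV enrichment pipeline applied to a table whose
    channels encode the two conditions; ``restrict_to`` limits the analysis to
    a prior protein set (e.g. proteins called RNA-interacting in a previous
    enrichment run); None analyses every protein ("extended list").
    """
    if restrict_to is not None:
        if not restrict_to:
            raise ValueError("restriction set is empty")
        table = table[table["Leading razor protein"].isin(restrict_to)]
        if table.empty:
            raise ValueError("no peptides left after restriction")
    return run_enrichment(table, design, params, min_peptides, min_experiments, alpha)
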