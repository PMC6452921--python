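# Methods

This note documents the models and procedures trappkit implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not
demonstrate.

## Background

UV irradiation crosslinks RNA to proteins in direct contact with it.  In the
4-thiouracil (4tU) variant of these protocols, cells incorporate the
photoactivatable analogue 4-thiouridine into RNA and are irradiated at
~350 nm, crosslinking 4tU to nearby residues.  Two computational problems
follow:

1. **Site identification.**  After nuclease P1 digestion (which leaves
   nucleoside 5'-monophosphates), crosslinked peptides carry a short RNA
   adduct.  Tandem-MS spectra of such conjugates must be searched with the
   adduct treated as a *cleavable* modification: the precursor carries the
   full adduct mass, while fragment ions retain either nothing, the full
   adduct, or a 4tU-derived stub.
2. **Enrichment quantification.**  SILAC-labelled irradiated and control
   cultures are mixed per experiment; the +UV/-UV intensity ratio of each
   peptide measures UV-dependent recovery, and proteins significantly above
   1:1 are called RNA-associated.

## Mass arithmetic (`trappkit.chem`)

All masses derive from a central monoisotopic atomic-mass table (CODATA/NIST
values, >= 8 significant decimals) through `MolecularFormula` arithmetic;
no derived mass is an inline literal.  Nucleotides are modelled as free-acid
nucleoside 5'-monophosphates; 4tU is uridine with one oxygen replaced by
sulfur.  An adduct of n nucleotides is the sum of monophosphate masses minus
(n-1) waters (phosphodiester condensation), plus one of six neutral states:
none, -H2S, -HPO3, -HPO3-H2S, +HPO3, +HPO3-H2S.  The loss of H2S is the
signature of the 4tU crosslink chemistry; the +HPO3 states describe the
frequently observed diphosphorylated species.

The retained-stub set contains exactly eight masses: the 4-thiouracil base,
base-H2S, and the 4tU monophosphate under the six neutral states.  Golden
tests compare these to their published values at 2e-5 Da, a tolerance that
absorbs drift between atomic-mass table editions.

The targeted adduct space is every multiset of 1-3 nucleotides over
{A, C, G, U, 4tU} containing at least one 4tU (the crosslink is assumed to
form through 4tU), crossed with the neutral states.  The single-nucleotide
slice of this table (6 adducts) is the default search space in the
benchmarks; the enumeration itself is verified against brute force.

## Digestion and decoys (`trappkit.digest`)

Trypsin cleavage C-terminal to K/R, by default also before proline (the
trypsin\P convention); classical behavior is a flag.  Defaults: <= 2 missed
cleavages, minimum length 6.  Fixed cysteine carbamidomethylation
(+57.021464 Da, derived from C2H3NO) reflects iodoacetamide alkylation;
carboxymethyl is selectable.  Variable methionine oxidation up to 2 per
peptide.  Amino-acid residue masses come from pyteomics.

Decoys are per-protein reversals (default) or tryptic-segment shuffles that
keep each segment's C-terminal K/R, so decoy peptides remain tryptic and
their mass distribution matches the targets.  Decoy identifiers carry the
`REV_` prefix.

## Crosslink search (`trappkit.search`)

**Candidates.**  Peptide candidates (all modification variants) x adducts are
indexed by peptide + adduct precursor mass; a spectrum's uncharged mass
(z·m/z − z·proton) selects candidates within the MS1 tolerance (6 ppm
default).  Targets and decoys compete in one pool.

**Fragments.**  For a candidate crosslinked at site s, b_i ions with i >= s
and y_j ions with j >= n-s+1 span the site and are emitted once per stub in
{complete loss, full adduct} ∪ the eight retained stubs; non-spanning ions
carry nothing.  Fragment charges 1-2, at most one neutral loss (H2O gated on
S/T/E/D content, NH3 on R/K/N/Q), and optionally additional match windows at
±1 neutron/z (the "off by 1 Da" setting, on by default and
score-contributing).

**Score.**  The match score is -log10 P(X >= k) for X ~ Binomial(N, p),
where N is the number of theoretical fragments, k the number of *distinct*
peaks matched by at least one fragment (each peak counts once — this is the
deterministic, monotone reading of unique matching), and p the per-fragment
chance of a random hit, estimated as peak density times the mean tolerance
window (times 3 when the ±1 Da windows are active).  The tail is evaluated
through the regularized incomplete beta function, falling back to log-space
pmf summation when it underflows; a naive survival function collapses to
zero for near-complete matches and cannot rank sites.  Fragment coverage is
the fraction of inter-residue bonds supported by a matched b/y ion.

**Localization.**  Site scores differ only through stub-bearing ions.  The
site is reported as localized only when exactly one site attains the top
score *and* that site has at least one matched stub-bearing fragment;
otherwise the PSM's site is undefined, and undefined-site PSMs are dropped
before site-level reporting.

**FDR.**  PSMs are sorted by descending score, decoys before targets on
ties (conservative); running FDR_i = decoys_i / max(targets_i, 1); q-values
are the cumulative minimum from the bottom; the accepted set is the largest
prefix with q <= threshold (1% default).

**Deduplication.**  Accepted PSMs collapse first to the best score per
(protein, absolute residue), then to the best score per (peptide sequence,
adduct), yielding unique crosslink sites.  Both steps mirror the duplicate
filters used in site-level reporting of crosslink studies.

## SILAC quantification (`trappkit.silac`)

Rows flagged as decoy or contaminant are removed.  Missing intensities
(NaN or 0) are imputed per channel (experiment x label) from a Gaussian on
the log2 scale centered at the channel's q-quantile of observed values
(q = 0.1), with standard deviation tune_sigma times the median of
per-channel observed standard deviations.  Presets: `par-trapp`
(tune_sigma = 0.01) and `trapp-yeast` (0.0035); smaller tune_sigma gives
tighter left-censored draws.  The exact internal scaling of the upstream
imputation package is not published; the definition above is this package's
normative one, preserving the q/tune_sigma semantics.  Peptides missing both
channels of an experiment are reset to missing afterwards — one observed
channel plus one imputed value is deliberately kept, since "+UV only"
peptides are exactly the strongly UV-enriched ones.

Ratios orient the irradiated channel as numerator (forward experiments:
light/heavy; reverse: heavy/light), so results are invariant under a full
label swap.  Protein ratios are the median over peptides (leading razor
protein as the grouping key) on the ratio scale, then log2-transformed;
proteins need >= 2 peptides in >= 2 experiments.

Significance uses a one-sample empirical-Bayes moderated t-test against 0:
the prior (d0, s0²) is moment-matched on log sample variances (digamma /
trigamma correction, trigamma inverted by Newton iteration); the posterior
variance is (d0·s0² + d·s²)/(d0 + d) and t has d0 + d degrees of freedom.
The implementation agrees with the reference empirical-Bayes implementation
(limma's eBayes) to machine precision on shared fixtures — that agreement is
a test, not a dependency.  Degenerate inputs (fewer than two positive sample
variances) fall back to the ordinary t-test.  Multiple testing is
Benjamini-Hochberg; the enriched call is adjusted p < 0.05 with positive
log2 ratio.  The differential mode applies the same machinery to
condition-vs-condition tables, optionally restricted to a prior protein set.

One open choice: the median over peptides is taken on the ratio scale before
the log2 transform (the order only matters for even peptide counts).

## Site statistics (`trappkit.sitestats`)

*Crosslink efficiency* per amino acid is its frequency at crosslink sites
divided by its frequency in all crosslinked peptide sequences (residues with
multiplicity, each surviving unique peptide counted once); residues absent
from the pool are omitted rather than divided by zero.

*Colocalization.*  Observed counts of crosslink sites within 20 residues of
a same-protein phosphosite versus outside are compared to expected counts
from 100 shuffles in which each protein's phosphosites are redrawn uniformly
without replacement over its residues (optionally restricted to S/T/Y);
a seeded generator replaces the original spreadsheet randomness.  The test
is a 1-df chi-square of observed versus mean-expected over the two
categories, no continuity correction.  With expected counts equal to the
null means, the statistic is approximately (O−E)²/Var(O) whenever per-site
inside-probabilities are homogeneous, hence approximately calibrated; strong
heterogeneity makes it mildly conservative.  Proteins without phosphosites
contribute only outside counts.  Zero expected counts raise an error
recommending more shuffles.

*Abundance bins.*  Proteins are sorted by abundance into 10 equal-count bins
(remainder spread over the top bins); each bin reports its median abundance
and enriched/(enriched + detected non-enriched), where non-enriched means
quantified (>= 2 peptides in >= 2 experiments) but not significant.

## Synthetic data (`trappkit.simulate`)

Every generator is a pure function of configuration + seed and returns a
truth record sufficient to score any downstream stage.

*Proteomes*: random sequences, gamma-distributed lengths (mean 300 by
default; the benchmarks use 150 to keep search spaces small), K+R at 10%
so tryptic peptides average ~10 residues.

*Conjugate spectra*: the candidate's own theoretical fragment set (unique
m/z values) sampled at a detection probability (default 0.7), Gaussian ppm
error (default 5 ppm at MS2, against a 20 ppm search tolerance), uniform
noise peaks (default 50 over 100-1800 Th), exponential intensities
(intensity is cosmetic: the score does not use it), precursor charge 2-4.

*SILAC tables*: protein log2 abundance ~ N(26, 2) with peptide-level spread
(sd 1), channel noise sd 0.25 log2 units, 1 + Poisson(3) peptides per
protein, three experiments (two forward, one reverse), 10% binders with
log2 effect 2 added to the irradiated channel.  Missingness is logistic in
log2 intensity (midpoint 23, slope 1.5 per log2 unit), i.e. smooth left
censoring — low-intensity signals preferentially drop out, the
missing-not-at-random structure that motivates left-censored imputation.
A hard threshold is the slope → ∞ limit.

What these generators do **not** emulate: chromatography and co-elution,
isotope envelopes, ratio compression from requantification, shared/razor
peptide ambiguity (each synthetic peptide belongs to one protein), and
sequence-dependent ionization.  Passing benchmarks therefore demonstrate
the correctness and calibration of the statistical machinery under its
stated model, not end-to-end performance on instrument data.

## Benchmark experiments (`trappkit.benchmarks`)

Problem sizes were chosen to exercise each claim at a desk scale:

- *Planted recovery*: 200 noiseless conjugate spectra over a 100-protein
  proteome (~150 aa each) with reversed decoys; exact rank-1 recovery of
  (peptide, adduct, site) is expected >= 99%.
- *FDR calibration*: 20 seeded runs of 150 realistic planted + 100
  pure-noise spectra over a 50-protein proteome; pooled realized false
  discovery proportion at the 1% decoy threshold should stay <= 2%.  The
  planted count is sized away from the D/T granularity boundary (where a
  single affordable decoy extends acceptance to the next decoy) so the
  accepted set behaves stably.
- *Null calibration of the moderated test*: 5000 proteins x 3 ratios drawn
  from the hierarchical null (sigma² scaled inverse-chi-square, d0=4,
  s0=0.3); the raw p < 0.05 fraction should sit in the binomial 99% CI of
  0.05 and BH calls should be near zero.
- *Power*: 10 seeded full-pipeline runs at 400 proteins, 10% binders,
  log2 effect 2; sensitivity >= 90% at realized FDR <= 10%.
- *Colocalization*: 500 null datasets (30 proteins x 400 aa, 3 phosphosites,
  2 sites each) for the type-I rate, and 100 planted datasets (sites within
  ±5 of phosphosites) for power.

`scripts/acceptance.py --seed S --out results/acceptance.json` reruns all of
these from scratch and writes the measured numbers.

## Known limitations

- The search assumes one adduct per PSM and localizes to a single residue;
  hydrogen losses at the crosslink bond are not modelled.
- Protein inference stops at the leading-protein assignment; shared peptides
  collapse in site deduplication rather than through protein grouping.
- The binomial score ignores peak intensity; intensity-aware rescoring is
  out of scope.
- The colocalization chi-square relies on the homogeneity argument above;
  for very heterogeneous protein lengths a full permutation p-value would be
  preferable to the chi-square approximation.
- Isotope-error correction on precursors is off by default; spectra whose
  reported precursor is a 13C peak will miss their candidate window.
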