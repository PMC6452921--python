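"""In-silico tryptic digestion, peptide modifications, and decoy databases."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from pyteomics.mass import std_aa_mass

from .chem import ELEMENT_MASSES, F, monoisotopic_mass

__all__ = [
    "ProteinRecord",
    "PeptideCandidate",
    "CARBAMIDOMETHYL_DELTA",
    "CARBOXYMETHYL_DELTA",
    "OXIDATION_DELTA",
    "WATER_MASS",
    "DECOY_PREFIX",
    "tryptic_digest",
    "apply_modifications",
    "generate_decoys",
    "digest_database",
    "residue_masses",
]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

DECOY_PREFIX = "REV_"

WATER_MASS = monoisotopic_mass(F("H2O"))
# Cys alkylation: carbamidomethyl (iodoacetamide, +C2H3NO) is the default;
# carboxymethyl (+C2H2O2) is selectable.
CARBAMIDOMETHYL_DELTA = monoisotopic_mass(F("C2H3NO"))
CARBOXYMETHYL_DELTA = monoisotopic_mass(F("C2H2O2"))
OXIDATION_DELTA = ELEMENT_MASSES["O"]


@dataclass(frozen=True)
class ProteinRecord:
    identifier: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.identifier!r}")


@dataclass(frozen=True)
class PeptideCandidate:
    """A tryptic peptide, optionally modified, with its neutral mass.

    ``start`` is the 1-based position of the first residue in the parent
    protein.  ``oxidized_met`` holds 1-based positions within the peptide.
    """

    sequence: str
    protein_id: str
    start: int
    missed_cleavages: int
    mass: float
    n_fixed_cys: int = 0
    oxidized_met: tuple[int, ...] = ()
    is_decoy: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def residue_masses(peptide: PeptideCandidate, fixed_cys_delta: float = CARBAMIDOMETHYL_DELTA) -> np.ndarray:
    """Per-residue monoisotopic masses including the peptide's modifications."""
    masses = np.array([std_aa_mass[aa] for aa in peptide.sequence])
    for i, aa in enumerate(peptide.sequence):
        if aa == "C":
            masses[i] += fixed_cys_delta
    for pos in peptide.oxidized_met:
        masses[pos - 1] += OXIDATION_DELTA
    return masses


def _peptide_mass(sequence: str) -> float:
    return sum(std_aa_mass[aa] for aa in sequence) + WATER_MASS


def tryptic_digest(
    protein: ProteinRecord,
    max_missed: int = 2,
    min_len: int = 6,
    cleave_before_proline: bool = True,
) -> list[PeptideCandidate]:
    """Digest with trypsin (C-terminal to K/R).

    ``cleave_before_proline=True`` is the trypsin\\P convention: K/R-P bonds
    are cleaved too.  Returns every peptide with 0..max_missed internal missed
    cleavage sites and length >= min_len, unmodified.
    """
    seq = protein.sequence
    for i, aa in enumerate(seq):
        if aa not in VALID_RESIDUES:
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1} in {protein.identifier}")
    cut_after = [
        i
        for i, aa in enumerate(seq)
        if aa in "KR" and (cleave_before_proline or i + 1 >= len(seq) or seq[i + 1] != "P")
    ]
    # segment boundaries: starts of fully cleaved segments
    starts = [0] + [i + 1 for i in cut_after if i + 1 < len(seq)]
    ends = [i + 1 for i in cut_after if i + 1 < len(seq)] + [len(seq)]
    peptides = []
    n_seg = len(starts)
    for first in range(n_seg):
        for last in range(first, min(first + max_missed + 1, n_seg)):
            s, e = starts[first], ends[last]
            pep = seq[s:e]
            if len(pep) < min_len:
                continue
            peptides.append(
                PeptideCandidate(
                    sequence=pep,
                    protein_id=protein.identifier,
                    start=s + 1,
                    missed_cleavages=last - first,
                    mass=_peptide_mass(pep),
                    is_decoy=protein.is_decoy,
                )
            )
    return peptides


def apply_modifications(
    peptide: PeptideCandidate,
    fixed_cys_delta: float = CARBAMIDOMETHYL_DELTA,
    allow_met_oxidation: bool = True,
    max_oxidations: int = 2,
) -> list[PeptideCandidate]:
    """Expand a peptide into its modification variants.

    The fixed Cys delta is applied to every cysteine; one variant is emitted
    per subset of oxidized methionines up to ``max_oxidations``.
    """
    n_cys = peptide.sequence.count("C")
    base_mass = peptide.mass + n_cys * fixed_cys_delta
    met_positions = [i + 1 for i, aa in enumerate(peptide.sequence) if aa == "M"]
    variants = [replace(peptide, mass=base_mass, n_fixed_cys=n_cys)]
    if allow_met_oxidation:
        for k in range(1, min(max_oxidations, len(met_positions)) + 1):
            for subset in itertools.combinations(met_positions, k):
                variants.append(
                    replace(
                        peptide,
                        mass=base_mass + k * OXIDATION_DELTA,
                        n_fixed_cys=n_cys,
                        oxidized_met=subset,
                    )
                )
    return variants


def _shuffle_segment_preserving_terminus(segment: str, rng: np.random.Generator) -> str:
    # keep the C-terminal K/R in place so decoy peptides stay tryptic
    if len(segment) > 1 and segment[-1] in "KR":
        body = list(segment[:-1])
        rng.shuffle(body)
        return "".join(body) + segment[-1]
    body = list(segment)
    rng.shuffle(body)
    return "".join(body)


def generate_decoys(
    database: list[ProteinRecord],
    mode: str = "reverse",
    seed: int = 0,
) -> list[ProteinRecord]:
    """One decoy per target protein: exact reversal, or tryptic-segment shuffle.

    Shuffle mode permutes residues within each tryptic segment, keeping the
    segment's C-terminal K/R fixed, so the decoy peptide mass distribution
    matches the target's.
    """
    if not database:
        raise ValueError("target database is empty")
    rng = np.random.default_rng(seed)
    decoys = []
    for protein in database:
        if mode == "reverse":
            decoy_seq = protein.sequence[::-1]
        elif mode == "shuffle":
            seq = protein.sequence
            segments = []
            start = 0
            for i, aa in enumerate(seq):
                if aa in "KR":
                    segments.append(seq[start : i + 1])
                    start = i + 1
            if start < len(seq):
                segments.append(seq[start:])
            decoy_seq = "".join(_shuffle_segment_preserving_terminus(s, rng) for s in segments)
        else:
            raise ValueError(f"unknown decoy mode {mode!r}")
        decoys.append(ProteinRecord(DECOY_PREFIX + protein.identifier, decoy_seq, is_decoy=True))
    return decoys


def digest_database(
    proteins: list[ProteinRecord],
    max_missed: int = 2,
    min_len: int = 6,
    cleave_before_proline: bool = True,
    fixed_cys_delta: float = CARBAMIDOMETHYL_DELTA,
    allow_met_oxidation: bool = True,
    max_oxidations: int = 2,
) -> list[PeptideCandidate]:
    """Digest a (target + decoy) database into modified peptide candidates."""
    out: list[PeptideCandidate] = []
    for protein in proteins:
        for pep in tryptic_digest(protein, max_missed, min_len, cleave_before_proline):
            out.extend(
                apply_modifications(pep, fixed_cys_delta, allow_met_oxidation, max_oxidations)
            )
    return out
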