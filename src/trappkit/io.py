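"""Format readers/writers and the run manifest.

FASTA goes through Biopython, MGF through pyteomics; tables are plain
tab-separated files with stable column order so identical runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as pymgf

from .digest import DECOY_PREFIX, VALID_RESIDUES, ProteinRecord
from .search import CrosslinkPSM, CrosslinkSite, SpectrumRecord

logger = logging.getLogger("trappkit")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_mgf",
    "write_mgf",
    "read_design",
    "write_design",
    "write_psm_table",
    "write_site_table",
    "read_config",
    "write_run_manifest",
]


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA; identifiers are headers up to first whitespace."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        identifier = rec.id
        seq = str(rec.seq).upper()
        if identifier in seen:
            raise ValueError(f"duplicate identifier {identifier!r} in {path}")
        seen.add(identifier)
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ValueError(f"illegal residues {sorted(bad)} in {identifier!r}")
        records.append(
            ProteinRecord(identifier, seq, is_decoy=identifier.startswith(DECOY_PREFIX))
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.identifier, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_mgf(path) -> list[SpectrumRecord]:
    """Read MS2 peak lists from Mascot Generic Format.

    Handles the "2+" and "2" charge dialects; blocks without a parseable
    precursor are skipped with a logged warning.
    """
    spectra = []
    skipped = 0
    with pymgf.MGF(str(path)) as reader:
        for i, spec in enumerate(reader):
            params = spec.get("params", {})
            title = str(params.get("title", f"index={i}"))
            try:
                pepmass = params["pepmass"][0]
                charge = int(params["charge"][0])
                spectra.append(
                    SpectrumRecord(
                        title, float(pepmass), charge, spec["m/z array"], spec["intensity array"]
                    )
                )
            except (KeyError, IndexError, TypeError, ValueError) as exc:
                skipped += 1
                logger.warning("skipping spectrum %r: %s", title, exc)
    if skipped:
        logger.warning("skipped %d unparseable spectra in %s", skipped, path)
    if not spectra:
        raise ValueError(f"no valid spectra in {path}")
    return spectra


def write_mgf(spectra: list[SpectrumRecord], path) -> None:
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": s.spectrum_id,
                "pepmass": s.precursor_mz,
                "charge": f"{s.charge}+",
            },
        }
        for s in spectra
    ]
    pymgf.write(entries, str(path), file_mode="w")


def read_design(path) -> dict[str, str]:
    """Experiment design: tab-separated ``experiment<TAB>orientation`` lines."""
    design = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or fields[1] not in ("forward", "reverse"):
                raise ValueError(f"bad design line {line!r}; expected 'exp<TAB>forward|reverse'")
            design[fields[0]] = fields[1]
    if not design:
        raise ValueError(f"empty design file {path}")
    return design


def write_design(design: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for exp in sorted(design):
            fh.write(f"{exp}\t{design[exp]}\n")


_PSM_COLUMNS = [
    "spectrum_id", "peptide", "protein", "start", "missed_cleavages",
    "adduct", "site", "score", "coverage", "matched_peaks", "is_decoy",
]


def write_psm_table(psms: list[CrosslinkPSM], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PSM_COLUMNS) + "\n")
        for p in psms:
            fh.write(
                "\t".join(
                    [
                        p.spectrum_id,
                        p.peptide.sequence,
                        p.peptide.protein_id,
                        str(p.peptide.start),
                        str(p.peptide.missed_cleavages),
                        p.adduct.label,
                        str(p.site) if p.site is not None else "undefined",
                        f"{p.score:.4f}",
                        f"{p.coverage:.4f}",
                        str(p.matched_peaks),
                        "+" if p.is_decoy else "",
                    ]
                )
                + "\n"
            )


_SITE_COLUMNS = [
    "protein", "position", "amino_acid", "adduct", "score", "peptide", "missed_cleavages",
]


def write_site_table(sites: list[CrosslinkSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SITE_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                "\t".join(
                    [
                        s.protein_id,
                        str(s.position),
                        s.amino_acid,
                        s.adduct_label,
                        f"{s.score:.4f}",
                        s.peptide_sequence,
                        str(s.missed_cleavages),
                    ]
                )
                + "\n"
            )


def read_config(path) -> dict:
    """YAML (or key: value) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(out_dir, command: str, config: dict, seed: int | None, inputs: list) -> Path:
    """Key-value run manifest: versions, config echo, seed, input digests."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_manifest.txt"
    with open(path, "w") as fh:
        fh.write(f"command\t{command}\n")
        fh.write(f"trappkit_version\t{__version__}\n")
        fh.write(f"python_version\t{sys.version.split()[0]}\n")
        fh.write(f"numpy_version\t{np.__version__}\n")
        fh.write(f"pandas_version\t{pd.__version__}\n")
        fh.write(f"seed\t{seed if seed is not None else ''}\n")
        for key in sorted(config):
            fh.write(f"config.{key}\t{config[key]}\n")
        for p in inputs:
            fh.write(f"input.{Path(p).name}\tsha256:{_sha256(Path(p))}\n")
    return path
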