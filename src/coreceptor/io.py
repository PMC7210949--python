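"""Shared readers and writers.

Conventions used by every file interface in the package: residue numbering is
1-based inclusive, distances are in Å, energies in kcal/mol, ligand
concentrations in nM, times in ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .seqann import DisorderProfile, ProteinRecord


# ---------------------------------------------------------------------------
# sequences and disorder profiles
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, offsets: dict[str, int] | None = None) -> list[ProteinRecord]:
    """Read a multi-record FASTA into :class:`ProteinRecord` objects.

    ``offsets`` optionally assigns extra-N-terminal-residue counts by record
    id (construct numbering vs canonical numbering).
    """
    offsets = offsets or {}
    records = [
        ProteinRecord(id=r.id, sequence=str(r.seq).upper(), offset=offsets.get(r.id, 0))
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_disorder_tsv(path: str | Path, protein_id: str | None = None) -> DisorderProfile:
    """Read a per-residue disorder score profile.

    Accepts 2-column TSV (position, score) or IUPred-style 3-column output
    (position, residue, score) with ``#`` comment/header lines.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            rows.append(parts)
    if not rows:
        raise ValueError(f"no scores found in {path}")
    # score is the last numeric column; position the first
    positions = [int(r[0]) for r in rows]
    scores = [float(r[-1]) for r in rows]
    order = np.argsort(positions)
    scores = [scores[i] for i in order]
    pid = protein_id if protein_id is not None else Path(path).stem
    return DisorderProfile(protein_id=pid, scores=scores)


def read_sites_csv(path: str | Path, column: str = "position") -> list[int]:
    """Read a plain CSV of residue positions (e.g. ubiquitylation sites)."""
    df = pd.read_csv(path)
    if column not in df.columns:
        # single unnamed column fallback
        if df.shape[1] == 1:
            column = df.columns[0]
        else:
            raise ValueError(f"column {column!r} not found in {path}")
    return [int(x) for x in df[column]]


# ---------------------------------------------------------------------------
# coarse structures (Cα bead models)
# ---------------------------------------------------------------------------

@dataclass
class CoarseStructure:
    """Labeled Cα beads of one rigid body.

    ``beads`` is a list of (chain, residue) tuples aligned with the ``coords``
    array (n, 3) in Å. A uniform bead radius is carried for clash checks.
    """

    beads: list[tuple[str, int]]
    coords: np.ndarray
    radius: float = 1.9

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.beads), 3)
        if len(self.beads) < 1:
            raise ValueError("structure needs at least one bead")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def index_of(self, chain: str, residue: int) -> int:
        try:
            return self.beads.index((chain, residue))
        except ValueError:
            raise KeyError(f"no CA bead for chain {chain} residue {residue}") from None


def read_pdb_ca(path: str | Path, radius: float = 1.9) -> CoarseStructure:
    """Extract Cα beads from a PDB file (ATOM records; HETATM ignored;
    first altloc kept)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    beads: list[tuple[str, int]] = []
    coords: list[list[float]] = []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.het_flag == "H":
                continue
            ca = res.find_atom("CA", "*")
            if ca is None:
                continue
            key = (chain.name, res.seqid.num)
            if key in beads:  # altloc duplicates: first kept
                continue
            beads.append(key)
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if not beads:
        raise ValueError(f"no CA atoms found in {path}")
    return CoarseStructure(beads=beads, coords=np.array(coords), radius=radius)


def write_pdb_ca(structure: CoarseStructure, path: str | Path) -> None:
    """Write a minimal Cα-only PDB (fixed-column ATOM records)."""
    with open(path, "w") as fh:
        for i, ((chain, resid), (x, y, z)) in enumerate(
            zip(structure.beads, structure.coords), start=1
        ):
            fh.write(
                f"ATOM  {i:5d}  CA  ALA {chain:>1}{resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {'C':>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Threshold and path bundle for the umbrella pipeline runner."""

    disorder_lo: float = 0.4
    disorder_hi: float = 0.6
    hotspot_threshold: float = -1.0
    cluster_max_gap: int = 30
    dsbu_max_ca_ca: float = 30.0
    sec_tolerance: float = 0.10
    seed: int = 0
    paths: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def validate(self) -> None:
        if not (0.0 <= self.disorder_lo <= self.disorder_hi <= 1.0):
            raise ValueError("disorder thresholds must satisfy 0 <= lo <= hi <= 1")
        if self.cluster_max_gap < 0:
            raise ValueError("cluster_max_gap must be >= 0")
        if self.dsbu_max_ca_ca <= 0:
            raise ValueError("dsbu_max_ca_ca must be positive")
        if not (0 < self.sec_tolerance < 1):
            raise ValueError("sec_tolerance must be a fraction in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "disorder_lo": self.disorder_lo,
            "disorder_hi": self.disorder_hi,
            "hotspot_threshold": self.hotspot_threshold,
            "cluster_max_gap": self.cluster_max_gap,
            "dsbu_max_ca_ca": self.dsbu_max_ca_ca,
            "sec_tolerance": self.sec_tolerance,
            "seed": self.seed,
            "paths": dict(self.paths),
            "stages": list(self.stages),
        }


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON pipeline config (YAML is a JSON superset)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
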