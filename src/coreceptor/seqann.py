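"""AUX/IAA sequence segmentation and per-residue annotation.

Canonical AUX/IAA repressors are built from five modules that this module
recovers from sequence alone: an N-terminal DI ending at the conserved
Lys-Arg (KR) dipeptide, a variable linker, the core degron matched by the
family regex ``VGWPP-[VI]-[RG]-x(2)-R``, the intrinsically disordered degron
tail, and the C-terminal PB1 oligomerization domain whose start is earmarked
by the first VKV motif downstream of the degron.

All residue indices are 1-based inclusive. Spans tile the sequence without
gaps or overlaps whenever the protein is canonical (degron and VKV present).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

MODULE_ORDER = ("DI", "linker", "degron", "degron_tail", "PB1")

DEGRON_REGEX = re.compile(r"VGWPP[VI][RG]..R")
PB1_START_MOTIF = "VKV"

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Kyte & Doolittle hydropathy index per residue.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


@dataclass
class ProteinRecord:
    """A protein sequence with an optional N-terminal numbering offset.

    ``offset`` counts extra N-terminal residues of the construct relative to
    canonical numbering (e.g. purification-tag remnants); it is applied when
    exchanging residue indices with crosslink tables.
    """

    id: str
    sequence: str
    offset: int = 0
    has_nonstandard: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        if self.offset < 0:
            raise ValueError(f"{self.id}: offset must be >= 0")
        letters = set(self.sequence)
        bad = letters - STANDARD_AA - {"X"}
        if bad:
            raise ValueError(f"{self.id}: invalid residue letters {sorted(bad)}")
        if "X" in letters:
            self.has_nonstandard = True

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DisorderProfile:
    """Per-residue disorder probabilities in [0, 1] (IUPred-style scores)."""

    protein_id: str
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.scores) == 0:
            raise ValueError(f"{self.protein_id}: empty disorder profile")
        arr = np.asarray(self.scores, dtype=float)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"{self.protein_id}: disorder scores outside [0, 1]")


@dataclass
class DomainAnnotation:
    """1-based inclusive module spans of one AUX/IAA.

    ``spans`` maps module names (subset of :data:`MODULE_ORDER`) to
    ``(start, end)``. ``canonical`` is True when the degron and the PB1-start
    motif were both found, in which case the spans tile the whole sequence.
    """

    protein_id: str
    length: int
    spans: dict[str, tuple[int, int]]
    kr_position: int | None = None
    canonical: bool = False

    def __post_init__(self) -> None:
        prev_end = 0
        for name in MODULE_ORDER:
            if name not in self.spans:
                continue
            start, end = self.spans[name]
            if not (1 <= start <= end <= self.length):
                raise ValueError(f"{self.protein_id}: span {name}={start, end} out of range")
            if start <= prev_end:
                raise ValueError(f"{self.protein_id}: overlapping/misordered span {name}")
            prev_end = end

    def module_of(self, position: int) -> str | None:
        """Module containing ``position``, or None (out of span / sequence)."""
        for name, (start, end) in self.spans.items():
            if start <= position <= end:
                return name
        return None


@dataclass
class SiteMap:
    """Residue positions (e.g. ubiquitylation sites) mapped onto modules."""

    protein_id: str
    positions: list[int]
    assignments: dict[int, str | None]
    per_domain_counts: dict[str, int]
    out_of_range: list[int]


def segment_domains(rec: ProteinRecord) -> DomainAnnotation:
    """Segment a sequence into DI / linker / degron / degron tail / PB1.

    The core degron is the first match of ``VGWPP-[VI]-[RG]-x(2)-R`` (a
    10-residue span; see :func:`extended_degron_span` for the 13-residue
    display convention). DI runs from residue 1 through the first KR
    dipeptide upstream of the degron; the PB1 domain starts at the first VKV
    motif at or after the degron end. When the degron or VKV is absent the
    annotation is partial and flagged non-canonical.
    """
    seq = rec.sequence
    n = len(seq)
    spans: dict[str, tuple[int, int]] = {}
    kr_position: int | None = None

    matches = list(DEGRON_REGEX.finditer(seq))
    if len(matches) > 1:
        warnings.warn(
            f"{rec.id}: {len(matches)} degron matches; using the first",
            stacklevel=2,
        )
    if not matches:
        return DomainAnnotation(
            protein_id=rec.id, length=n, spans={}, kr_position=None, canonical=False
        )
    m = matches[0]
    deg_start, deg_end = m.start() + 1, m.end()  # 1-based inclusive
    spans["degron"] = (deg_start, deg_end)

    # first KR dipeptide strictly upstream of the degron
    kr_idx = seq.find("KR", 0, deg_start - 1)
    if kr_idx >= 0 and kr_idx + 2 <= deg_start - 1:
        kr_position = kr_idx + 1
        spans["DI"] = (1, kr_idx + 2)  # through the R of the KR dipeptide
        if kr_idx + 3 <= deg_start - 1:
            spans["linker"] = (kr_idx + 3, deg_start - 1)
    else:
        # no KR: DI empty, linker takes the whole N-terminal stretch
        if deg_start > 1:
            spans["linker"] = (1, deg_start - 1)

    # PB1 starts at the first VKV at/after the degron end
    vkv_idx = seq.find(PB1_START_MOTIF, deg_end)
    if vkv_idx < 0:
        return DomainAnnotation(
            protein_id=rec.id,
            length=n,
            spans=spans,
            kr_position=kr_position,
            canonical=False,
        )
    pb1_start = vkv_idx + 1
    if pb1_start > deg_end + 1:
        spans["degron_tail"] = (deg_end + 1, pb1_start - 1)
    spans["PB1"] = (pb1_start, n)
    return DomainAnnotation(
        protein_id=rec.id,
        length=n,
        spans=spans,
        kr_position=kr_position,
        canonical=True,
    )


def extended_degron_span(ann: DomainAnnotation, left_ext: int = 3) -> tuple[int, int]:
    """Degron span extended ``left_ext`` residues to the left.

    The family literature describes a 13-aa degron while the machine-checkable
    regex spans 10 residues; the default extension of 3 restores the 13-aa
    display convention. The extension is clipped at residue 1.
    """
    if "degron" not in ann.spans:
        raise ValueError(f"{ann.protein_id}: no degron span")
    start, end = ann.spans["degron"]
    return (max(1, start - left_ext), end)


def classify_disorder(
    prof: DisorderProfile,
    lo: float = 0.4,
    hi: float = 0.6,
    span: tuple[int, int] | None = None,
) -> tuple[list[str], dict[str, float]]:
    """Classify residues as disordered (> hi), ordered (< lo) or intermediate.

    The thresholds follow the standard IUPred-score convention with the
    boundary values 0.4 and 0.6 counted as intermediate (closed interval).
    ``span`` restricts the classification to a 1-based inclusive sub-span,
    e.g. to exclude the folded PB1 domain.

    Returns the per-residue category vector and the three fractions, which
    sum to 1.
    """
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("thresholds must satisfy 0 <= lo <= hi <= 1")
    scores = np.asarray(prof.scores, dtype=float)
    if span is not None:
        start, end = span
        if not (1 <= start <= end <= len(scores)):
            raise ValueError(f"span {span} outside profile of length {len(scores)}")
        scores = scores[start - 1 : end]
    cats = np.where(scores > hi, "disordered", np.where(scores < lo, "ordered", "intermediate"))
    n = len(scores)
    fractions = {
        "disordered": float(np.sum(cats == "disordered")) / n,
        "intermediate": float(np.sum(cats == "intermediate")) / n,
        "ordered": float(np.sum(cats == "ordered")) / n,
    }
    return list(cats), fractions


def hydropathy_profile(rec: ProteinRecord, window: int = 9) -> np.ndarray:
    """Kyte–Doolittle sliding-window hydropathy, one value per residue.

    The window must be odd; at the termini it shrinks symmetrically so the
    output has exactly the sequence length (no edge truncation).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    values = np.array([KYTE_DOOLITTLE[aa] for aa in rec.sequence])
    half = window // 2
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = values[i - h : i + h + 1].mean()
    return out


def lysine_positions(rec: ProteinRecord) -> list[int]:
    """All lysine positions (1-based) — the ubiquitin-acceptor inventory."""
    return [i + 1 for i, aa in enumerate(rec.sequence) if aa == "K"]


def map_sites(positions: list[int], ann: DomainAnnotation) -> SiteMap:
    """Assign residue positions (e.g. Ub sites) to their containing module.

    Positions outside the sequence are flagged in ``out_of_range`` rather
    than dropped. Span boundaries are inclusive on both ends.
    """
    assignments: dict[int, str | None] = {}
    counts: dict[str, int] = {name: 0 for name in ann.spans}
    out_of_range: list[int] = []
    for pos in positions:
        if not (1 <= pos <= ann.length):
            out_of_range.append(pos)
            assignments[pos] = None
            continue
        module = ann.module_of(pos)
        assignments[pos] = module
        if module is not None:
            counts[module] += 1
    return SiteMap(
        protein_id=ann.protein_id,
        positions=list(positions),
        assignments=assignments,
        per_domain_counts=counts,
        out_of_range=out_of_range,
    )


def degron_tail_length(ann: DomainAnnotation) -> int:
    """Residue count between the degron end and the PB1 start.

    Equals ``PB1.start − degron.end − 1``; zero when the PB1-start motif
    immediately follows the degron.
    """
    if not ann.canonical:
        raise ValueError(f"{ann.protein_id}: degron tail undefined for non-canonical annotation")
    return ann.spans["PB1"][0] - ann.spans["degron"][1] - 1
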