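"""Crosslink-MS tables, reproducibility filtering and distance restraints.

Residue–residue identifications from an MS-cleavable crosslinker (DSBU,
reactive toward K/S/T/Y and N-termini) are ingested from MeroX-style export
tables, corrected to canonical numbering, filtered by replicate support, and
turned into Cα–Cα distance restraints. A special polymer restraint encodes
the length of the disordered degron tail: its bounds are twice the
theoretical Stokes radius of the tail peptide in the folded (lower) and
fully disordered (upper) state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hydro import FoldClassBands, theoretical_rs
from .io import CoarseStructure

REQUIRED_XL_COLUMNS = ("protein1", "residue1", "protein2", "residue2", "replicate")

#: residues DSBU can react with (plus protein N-termini)
CROSSLINKABLE = set("KSTY")

#: default maximum Cα–Cα distance for a DSBU crosslink restraint (Å):
#: ~12.5 Å spacer plus side-chain and backbone flexibility allowances.
DSBU_MAX_CA_CA = 30.0

#: mean residue mass used to convert tail length (aa) to peptide mass (Da)
MEAN_RESIDUE_MASS_DA = 110.0


@dataclass(frozen=True)
class CrossLink:
    """One crosslink identification in canonical numbering.

    The unordered endpoint pair is the identity key: which peptide was the
    alpha or beta chain is ignored.
    """

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    replicate_id: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.residue_a < 1 or self.residue_b < 1:
            raise ValueError("residue indices must be >= 1")
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        a = (self.protein_a, self.residue_a)
        b = (self.protein_b, self.residue_b)
        return (a, b) if a <= b else (b, a)

    @property
    def is_intra(self) -> bool:
        return self.protein_a == self.protein_b


@dataclass
class XLNetwork:
    """Unique crosslinked pairs with their replicate support."""

    support: dict[tuple, set[str]]
    n_replicates: int
    replicate_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for pair, reps in self.support.items():
            extra = reps - self.replicate_ids
            if self.replicate_ids and extra:
                raise ValueError(f"pair {pair}: unknown replicates {sorted(extra)}")

    @property
    def pairs(self) -> list[tuple]:
        return sorted(self.support)


@dataclass
class DistanceRestraint:
    """A distance bound between two Cα anchors; source XL or TAIL."""

    anchor_a: tuple[str, int]  # (chain, residue)
    anchor_b: tuple[str, int]
    lower: float
    upper: float
    source: str = "XL"

    def __post_init__(self) -> None:
        if not (0 <= self.lower < self.upper):
            raise ValueError(f"need 0 <= lower < upper, got [{self.lower}, {self.upper}]")
        if self.source not in ("XL", "TAIL"):
            raise ValueError(f"unknown restraint source {self.source!r}")


@dataclass
class ClusterSpan:
    start: int
    end: int
    members: list[int]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if any(not (self.start <= m <= self.end) for m in self.members):
            raise ValueError("members must lie within [start, end]")


def load_xl_table(
    path: str | Path,
    offsets: dict[str, int] | None = None,
    sequences: dict[str, str] | None = None,
) -> list[CrossLink]:
    """Read a MeroX-export-like crosslink CSV.

    Requires columns protein1/residue1/protein2/residue2/replicate (score
    optional). ``offsets`` subtracts per-protein construct offsets so residue
    indices end up in canonical numbering; rows whose corrected index drops
    below 1 are discarded with a warning. If ``sequences`` is given, links at
    residues outside the DSBU-reactive vocabulary (K/S/T/Y or residue 1)
    trigger a warning only.
    """
    offsets = offsets or {}
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_XL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"crosslink table {path} missing columns: {missing}")
    links: list[CrossLink] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        ra = int(row.residue1) - offsets.get(str(row.protein1), 0)
        rb = int(row.residue2) - offsets.get(str(row.protein2), 0)
        if ra < 1 or rb < 1:
            n_dropped += 1
            continue
        links.append(
            CrossLink(
                protein_a=str(row.protein1),
                residue_a=ra,
                protein_b=str(row.protein2),
                residue_b=rb,
                replicate_id=str(row.replicate),
                score=float(getattr(row, "score", 0.0) or 0.0),
            )
        )
    if n_dropped:
        warnings.warn(
            f"{path}: {n_dropped} rows dropped (offset-corrected residue < 1)",
            stacklevel=2,
        )
    if sequences:
        for link in links:
            for prot, res in [(link.protein_a, link.residue_a), (link.protein_b, link.residue_b)]:
                seq = sequences.get(prot)
                if seq is None or res > len(seq) or res == 1:
                    continue
                if seq[res - 1] not in CROSSLINKABLE:
                    warnings.warn(
                        f"{prot} residue {res} ({seq[res - 1]}) is not a DSBU-reactive residue",
                        stacklevel=2,
                    )
    return links


def build_network(links: list[CrossLink], n_replicates: int | None = None) -> XLNetwork:
    """Group identifications by unordered endpoint pair and collect support."""
    support: dict[tuple, set[str]] = {}
    replicate_ids: set[str] = set()
    for link in links:
        support.setdefault(link.pair, set()).add(link.replicate_id)
        replicate_ids.add(link.replicate_id)
    n = n_replicates if n_replicates is not None else len(replicate_ids)
    return XLNetwork(support=support, n_replicates=n, replicate_ids=replicate_ids or set())


def replicate_filter(
    net: XLNetwork, min_support: int
) -> tuple[XLNetwork, dict[tuple, str]]:
    """Keep pairs seen in at least ``min_support`` replicates.

    Returns the filtered network and a support-class label per surviving
    pair: ``solid`` for unanimous support (seen in every replicate), else
    ``dashed`` — the convention used for reproducible crosslink maps.
    """
    if min_support > net.n_replicates:
        raise ValueError("min_support cannot exceed the number of replicates")
    kept = {p: r for p, r in net.support.items() if len(r) >= min_support}
    classes = {
        p: ("solid" if len(r) == net.n_replicates else "dashed") for p, r in kept.items()
    }
    filtered = XLNetwork(
        support=kept, n_replicates=net.n_replicates, replicate_ids=set(net.replicate_ids)
    )
    return filtered, classes


def classify_links(net: XLNetwork) -> tuple[list[tuple], list[tuple]]:
    """Partition pairs into (intra, inter) by protein identity."""
    intra = [p for p in net.pairs if p[0][0] == p[1][0]]
    inter = [p for p in net.pairs if p[0][0] != p[1][0]]
    return intra, inter


def cluster_residues(positions: list[int], max_gap: int = 30) -> list[ClusterSpan]:
    """Single-linkage 1D clustering of residue positions.

    Consecutive sorted positions join one cluster iff their gap is at most
    ``max_gap`` residues; each cluster is reported as its min–max span.
    """
    if not positions:
        raise ValueError("positions must be non-empty")
    sorted_pos = sorted(set(positions))
    clusters: list[list[int]] = [[sorted_pos[0]]]
    for pos in sorted_pos[1:]:
        if pos - clusters[-1][-1] <= max_gap:
            clusters[-1].append(pos)
        else:
            clusters.append([pos])
    return [ClusterSpan(start=c[0], end=c[-1], members=c) for c in clusters]


@dataclass
class RestraintReport:
    restraints: list[DistanceRestraint]
    unresolvable: list[tuple]
    satisfied: dict[int, bool]  # restraint index -> satisfied at current coords
    distances: dict[int, float]


def xl_to_restraints(
    net: XLNetwork,
    structures: dict[str, CoarseStructure],
    chain_of: dict[str, str],
    max_ca_ca: float = DSBU_MAX_CA_CA,
    lower: float = 0.0,
) -> RestraintReport:
    """Convert inter-protein crosslinks to Cα–Cα distance restraints.

    ``structures`` maps protein name to its bead model and ``chain_of`` maps
    protein name to its chain id in the restraint/anchor namespace. Links
    whose endpoints have no coordinates (e.g. residues inside an IDR that was
    not modelled) are listed as unresolvable, not fatal. For fully resolvable
    links the current Cα–Cα distance and a satisfied/violated flag are
    reported.
    """
    intra, inter = classify_links(net)
    restraints: list[DistanceRestraint] = []
    unresolvable: list[tuple] = []
    satisfied: dict[int, bool] = {}
    distances: dict[int, float] = {}
    for pair in inter:
        (prot_a, res_a), (prot_b, res_b) = pair
        coords = []
        ok = True
        for prot, res in ((prot_a, res_a), (prot_b, res_b)):
            st = structures.get(prot)
            if st is None:
                ok = False
                break
            try:
                idx = st.index_of(chain_of.get(prot, prot), res)
            except KeyError:
                ok = False
                break
            coords.append(st.coords[idx])
        if not ok:
            unresolvable.append(pair)
            continue
        idx = len(restraints)
        restraints.append(
            DistanceRestraint(
                anchor_a=(chain_of.get(prot_a, prot_a), res_a),
                anchor_b=(chain_of.get(prot_b, prot_b), res_b),
                lower=lower,
                upper=max_ca_ca,
                source="XL",
            )
        )
        d = float(np.linalg.norm(coords[0] - coords[1]))
        distances[idx] = d
        satisfied[idx] = lower <= d <= max_ca_ca
    if not restraints:
        warnings.warn("no resolvable inter-protein crosslinks", stacklevel=2)
    return RestraintReport(
        restraints=restraints,
        unresolvable=unresolvable,
        satisfied=satisfied,
        distances=distances,
    )


def tail_restraint(
    tail_len_aa: int,
    anchor_a: tuple[str, int],
    anchor_b: tuple[str, int],
    bands: FoldClassBands,
    mean_residue_mass: float = MEAN_RESIDUE_MASS_DA,
    scale: float = 2.0,
) -> DistanceRestraint:
    """Polymer restraint encoding the disordered degron-tail length.

    The tail peptide mass is ``tail_len_aa × mean_residue_mass``; its
    theoretical Stokes radii in the folded (NF, minimum) and fully disordered
    (IDP, maximum) state bound the anchor separation, scaled by a geometry
    factor (default 2: end-to-end distance ≈ 2·Rs).
    """
    if tail_len_aa < 1:
        raise ValueError("tail length must be >= 1 aa")
    mass = tail_len_aa * mean_residue_mass
    lower = scale * theoretical_rs(mass, "NF", bands)
    upper = scale * theoretical_rs(mass, "IDP", bands)
    return DistanceRestraint(
        anchor_a=anchor_a, anchor_b=anchor_b, lower=lower, upper=upper, source="TAIL"
    )


def _tbl_line(r: DistanceRestraint) -> str:
    d = r.upper
    dminus = r.upper - r.lower
    return (
        f"assign (segid {r.anchor_a[0]} and resid {r.anchor_a[1]} and name CA) "
        f"(segid {r.anchor_b[0]} and resid {r.anchor_b[1]} and name CA) "
        f"{d:.1f} {dminus:.1f} {0.0:.1f}"
    )


def write_tbl(restraints: list[DistanceRestraint], path: str | Path,
              header_params: dict | None = None) -> None:
    """Write restraints in the ambiguous-distance ``assign`` dialect.

    Each line is ``assign (segid A and resid i and name CA) (segid B and
    resid j and name CA) d dminus dplus`` with d = upper, dminus = upper −
    lower, dplus = 0. Output ordering is byte-stable (sorted by anchors), and
    generation parameters go into comment lines.
    """
    if not restraints:
        raise ValueError("no restraints to write")
    ordered = sorted(restraints, key=lambda r: (r.anchor_a, r.anchor_b, r.source))
    with open(path, "w") as fh:
        if header_params:
            for key in sorted(header_params):
                fh.write(f"! {key} = {header_params[key]}\n")
        for r in ordered:
            fh.write(_tbl_line(r) + "\n")


def read_tbl(path: str | Path) -> list[DistanceRestraint]:
    """Parse back a restraint file written by :func:`write_tbl`."""
    import re

    pat = re.compile(
        r"assign \(segid (\S+) and resid (\d+) and name CA\) "
        r"\(segid (\S+) and resid (\d+) and name CA\) "
        r"([\d.]+) ([\d.]+) ([\d.]+)"
    )
    restraints = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("!") or not line.strip():
            continue
        m = pat.match(line.strip())
        if not m:
            raise ValueError(f"unparseable restraint line: {line!r}")
        ca, ra, cb, rb, d, dminus, _ = m.groups()
        upper = float(d)
        lower = upper - float(dminus)
        restraints.append(
            DistanceRestraint(
                anchor_a=(ca, int(ra)), anchor_b=(cb, int(rb)), lower=lower, upper=upper
            )
        )
    return restraints


def export_circular_map(
    net: XLNetwork, support_classes: dict[tuple, str] | None = None
) -> pd.DataFrame:
    """Flat link table for circos-style rendering.

    Columns: protein_a, res_a, protein_b, res_b, class (intra/inter),
    support_class (solid/dashed).
    """
    if support_classes is None:
        support_classes = {
            p: ("solid" if len(r) == net.n_replicates else "dashed")
            for p, r in net.support.items()
        }
    rows = []
    for pair in net.pairs:
        (pa, ra), (pb, rb) = pair
        rows.append(
            {
                "protein_a": pa,
                "res_a": ra,
                "protein_b": pb,
                "res_b": rb,
                "class": "intra" if pa == pb else "inter",
                "support_class": support_classes[pair],
            }
        )
    return pd.DataFrame(rows, columns=["protein_a", "res_a", "protein_b", "res_b", "class", "support_class"])
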