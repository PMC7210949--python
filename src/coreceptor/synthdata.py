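"""Seeded synthetic-data generators with planted ground truth.

Every pipeline stage gets a generator that emulates the corresponding
experimental data under known truth, so recovery tests can compare against
construction rather than against external data:

- sequences with planted KR / degron / VKV motifs and known module spans;
- saturation-binding count tables under the one-site total+nonspecific
  model with multiplicative (log-normal) noise;
- replicated crosslink tables with planted reproducible links and
  single-replicate decoys;
- toy receptor/ligand bead bodies with a brute-force placement census;
- ΔG_eff time series with an equilibration transient, per-residue
  decomposition tables with planted hot-spots, and paired wild-type/mutant
  series with planted ΔΔG.

All generators draw from a single explicitly seeded ``numpy`` Generator and
are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import BindingDataset, model_total
from .energetics import DecompositionTable, EnergyTrajectory
from .io import CoarseStructure
from .seqann import ProteinRecord
from .xlink import DistanceRestraint
from . import ispace

# alphabets that cannot create spurious motifs: upstream of the degron no Arg
# (so neither KR nor the degron regex can appear by chance), in the degron
# tail no Val (so neither VKV nor VGWPP can appear)
_UPSTREAM_AA = "ACDEFGHIKLMNPQSTWY"  # no R, no V (V excluded to avoid VGWPP seeds)
_TAIL_AA = "ACDEFGHIKLMNPQRSTWY"  # no V
_ANY_AA = "ACDEFGHIKLMNPQRSTVWY"


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str) -> str:
    if n == 0:
        return ""
    return "".join(rng.choice(list(alphabet), size=n))


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def gen_sequences(
    seed: int,
    n_records: int = 5,
    n_noncanonical: int = 0,
    di_len_range: tuple[int, int] = (10, 40),
    linker_len_range: tuple[int, int] = (4, 30),
    tail_len_range: tuple[int, int] = (0, 60),
    pb1_len_range: tuple[int, int] = (60, 100),
) -> tuple[list[ProteinRecord], dict]:
    """Random AUX/IAA-like sequences with planted module architecture.

    Each canonical record is DI (ending in the KR dipeptide) + linker +
    degron (a random realisation of VGWPP-[VI]-[RG]-x(2)-R) + degron tail +
    PB1 (starting with VKV). Alphabet restrictions upstream and in the tail
    guarantee no spurious motif occurrences, so planted spans are exact.
    Non-canonical records carry no degron. Truth lists the spans, the KR
    position and the tail length per record.
    """
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth: dict = {"records": {}}
    for i in range(n_records):
        di_len = int(rng.integers(*di_len_range))  # includes the KR dipeptide
        di_len = max(di_len, 2)
        linker_len = int(rng.integers(*linker_len_range))
        tail_len = int(rng.integers(tail_len_range[0], tail_len_range[1] + 1))
        pb1_len = int(rng.integers(*pb1_len_range))  # includes VKV
        pb1_len = max(pb1_len, 3)
        degron = (
            "VGWPP"
            + str(rng.choice(["V", "I"]))
            + str(rng.choice(["R", "G"]))
            + _rand_seq(rng, 2, _UPSTREAM_AA)
            + "R"
        )
        seq = (
            _rand_seq(rng, di_len - 2, _UPSTREAM_AA)
            + "KR"
            + _rand_seq(rng, linker_len, _UPSTREAM_AA)
            + degron
            + _rand_seq(rng, tail_len, _TAIL_AA)
            + "VKV"
            + _rand_seq(rng, pb1_len - 3, _ANY_AA)
        )
        rec = ProteinRecord(id=f"synth_{i:02d}", sequence=seq)
        deg_start = di_len + linker_len + 1
        deg_end = deg_start + 9
        pb1_start = deg_end + tail_len + 1
        spans = {"DI": (1, di_len), "degron": (deg_start, deg_end), "PB1": (pb1_start, len(seq))}
        if linker_len > 0:
            spans["linker"] = (di_len + 1, di_len + linker_len)
        if tail_len > 0:
            spans["degron_tail"] = (deg_end + 1, pb1_start - 1)
        records.append(rec)
        truth["records"][rec.id] = {
            "spans": spans,
            "kr_position": di_len - 1,
            "tail_len": tail_len,
            "canonical": True,
        }
    for i in range(n_noncanonical):
        n = int(rng.integers(80, 150))
        rec = ProteinRecord(id=f"synth_nc_{i:02d}", sequence=_rand_seq(rng, n, _UPSTREAM_AA))
        records.append(rec)
        truth["records"][rec.id] = {"spans": {}, "canonical": False}
    return records, truth


# ---------------------------------------------------------------------------
# saturation binding
# ---------------------------------------------------------------------------

#: 10 log-spaced concentrations 1–2000 nM, the default simulation design
DEFAULT_DESIGN_NM = np.geomspace(1.0, 2000.0, 10)


def gen_binding(
    seed: int,
    kd_nM: float,
    bmax: float = 1.0,
    ns: float = 5e-4,
    design_nM: np.ndarray | None = None,
    cv: float = 0.10,
    n_rep: int = 3,
) -> tuple[BindingDataset, dict]:
    """Synthetic saturation-binding counts with multiplicative noise.

    Total and nonspecific counts equal the one-site model values times a
    log-normal factor with unit mean and coefficient of variation ``cv``
    (``cv=0`` gives exact model values). Default design: 10 log-spaced
    concentrations 1–2000 nM in triplicate.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(design_nM if design_nM is not None else DEFAULT_DESIGN_NM, dtype=float)
    total_true = model_total(x, kd_nM, bmax, ns)
    ns_true = ns * x
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv**2))
        noise_t = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=(len(x), n_rep))
        noise_n = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=(len(x), n_rep))
    else:
        noise_t = np.ones((len(x), n_rep))
        noise_n = np.ones((len(x), n_rep))
    ds = BindingDataset(
        ligand_nM=x,
        total_counts=total_true[:, None] * noise_t,
        nonspecific_counts=ns_true[:, None] * noise_n,
        meta={"seed": seed},
    )
    truth = {"kd_nM": kd_nM, "bmax": bmax, "ns": ns, "cv": cv, "n_rep": n_rep}
    return ds, truth


# ---------------------------------------------------------------------------
# crosslink tables
# ---------------------------------------------------------------------------

def gen_xl_table(
    seed: int,
    n_replicates: int = 3,
    min_support: int = 2,
    n_true_inter: int = 8,
    n_decoys: int = 10,
    receptor: str = "TIR1",
    ligand: str = "IAA7",
    receptor_windows: tuple[tuple[int, int], ...] = ((140, 229), (485, 529)),
    ligand_degron: tuple[int, int] = (80, 92),
    ligand_length: int = 240,
) -> tuple[pd.DataFrame, dict]:
    """Replicated crosslink table with planted reproducible links and decoys.

    True inter-protein links join receptor residues drawn from two sequence
    windows (emulating the two crosslink-reactive clusters) to ligand
    residues up- or downstream of a nominal degron; each appears in at least
    ``min_support`` replicates. Decoys appear in exactly one replicate and
    never coincide with a planted pair. Truth records both sets.
    """
    if min_support > n_replicates:
        raise ValueError("min_support cannot exceed n_replicates")
    rng = np.random.default_rng(seed)
    replicates = [f"rep{i + 1}" for i in range(n_replicates)]
    planted: set[tuple[int, int]] = set()
    while len(planted) < n_true_inter:
        win = receptor_windows[int(rng.integers(len(receptor_windows)))]
        r_res = int(rng.integers(win[0], win[1] + 1))
        if rng.random() < 0.5:  # upstream of the degron
            l_res = int(rng.integers(1, ligand_degron[0]))
        else:  # downstream
            l_res = int(rng.integers(ligand_degron[1] + 1, ligand_length + 1))
        planted.add((r_res, l_res))
    decoys: set[tuple[int, int]] = set()
    while len(decoys) < n_decoys:
        pair = (int(rng.integers(1, 600)), int(rng.integers(1, ligand_length + 1)))
        if pair not in planted:
            decoys.add(pair)
    rows = []
    support_truth = {}
    for r_res, l_res in sorted(planted):
        k = int(rng.integers(min_support, n_replicates + 1))
        reps = list(rng.choice(replicates, size=k, replace=False))
        support_truth[(r_res, l_res)] = sorted(reps)
        for rep in reps:
            rows.append(
                {
                    "protein1": receptor,
                    "residue1": r_res,
                    "protein2": ligand,
                    "residue2": l_res,
                    "replicate": rep,
                    "score": float(np.round(rng.uniform(70, 200), 1)),
                }
            )
    for r_res, l_res in sorted(decoys):
        rep = str(rng.choice(replicates))
        rows.append(
            {
                "protein1": receptor,
                "residue1": r_res,
                "protein2": ligand,
                "residue2": l_res,
                "replicate": rep,
                "score": float(np.round(rng.uniform(70, 120), 1)),
            }
        )
    df = pd.DataFrame(rows)
    truth = {
        "planted": sorted(planted),
        "decoys": sorted(decoys),
        "support": {f"{a}-{b}": reps for (a, b), reps in support_truth.items()},
        "n_replicates": n_replicates,
        "min_support": min_support,
        "receptor_windows": list(receptor_windows),
    }
    return df, truth


# ---------------------------------------------------------------------------
# toy structures for the interaction-space scan
# ---------------------------------------------------------------------------

@dataclass
class ToyScenario:
    """A toy rigid-body instance with its scan parameters and truth census."""

    receptor: CoarseStructure
    ligand: CoarseStructure
    restraints: list[DistanceRestraint]
    scan_params: dict
    census: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)


def _brute_force_census(
    receptor: CoarseStructure,
    ligand: CoarseStructure,
    restraints: list[DistanceRestraint],
    scan_params: dict,
) -> dict[int, int]:
    """Naive triple-loop placement census over the identical placement set.

    Independent of the scanner's vectorized path: distances are evaluated
    with plain ``math.dist`` loops. Only usable for small instances.
    """
    grid = ispace.placement_grid(
        receptor.coords, scan_params["grid_spacing"], scan_params["padding"]
    )
    rotations = ispace.rotation_set(scan_params["n_rotations"])
    lig_local = ligand.coords - ligand.coords.mean(axis=0)
    anchors = []
    for r in restraints:
        ri = receptor.index_of(*r.anchor_a)
        li = ligand.index_of(*r.anchor_b)
        anchors.append((receptor.coords[ri], li, r.lower, r.upper))
    clash = scan_params["clash_dist"]
    counts = {k: 0 for k in range(len(restraints) + 1)}
    for rot in rotations:
        placed = [tuple(rot @ b) for b in lig_local]
        for center in grid:
            cx, cy, cz = center
            ok = True
            for bx, by, bz in placed:
                px, py, pz = cx + bx, cy + by, cz + bz
                for rxyz in receptor.coords:
                    if math.dist((px, py, pz), rxyz) < clash:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            nsat = 0
            for apos, li, lo, up in anchors:
                bx, by, bz = placed[li]
                d = math.dist((cx + bx, cy + by, cz + bz), apos)
                if lo <= d <= up:
                    nsat += 1
            counts[0] += 1
            for k in range(1, nsat + 1):
                counts[k] += 1
    return counts


def gen_toy_structures(seed: int, scenario: str = "census") -> ToyScenario:
    """Toy receptor/ligand bead bodies with known accessible placement sets.

    Scenarios:

    - ``census``: 2-bead receptor, 1-bead ligand, one restraint; small
      enough for exhaustive brute-force verification.
    - ``two_lobe``: a bead wall splits the accessible space into two lobes
      that both satisfy the generous crosslink restraints; a tight
      degron-tail restraint (applied last) removes one lobe, producing a
      sharp final drop in the restraint-application curve.
    - ``symmetric``: mirror-symmetric receptor and restraints, so every
      contacted residue has interaction propensity exactly 1.

    The seed is carried for interface uniformity; these geometries are
    deterministic constructions.
    """
    del seed  # geometries are fixed by construction
    if scenario == "census":
        receptor = CoarseStructure(
            beads=[("R", 1), ("R", 2)], coords=np.array([[0.0, 0, 0], [4.0, 0, 0]])
        )
        ligand = CoarseStructure(beads=[("L", 1)], coords=np.array([[0.0, 0, 0]]))
        restraints = [
            DistanceRestraint(anchor_a=("R", 1), anchor_b=("L", 1), lower=0.0, upper=6.0)
        ]
        params = {"grid_spacing": 2.0, "padding": 6.0, "n_rotations": 1,
                  "clash_dist": 3.0, "canonicalize": False}
        truth = {}
    elif scenario == "two_lobe":
        wall = [(float(0), float(y), float(z)) for y in (-6, -2, 2, 6) for z in (-6, -2, 2, 6)]
        coords = wall + [(-8.0, 0.0, 0.0), (8.0, 0.0, 0.0)]
        beads = [("R", i + 1) for i in range(len(wall))] + [("R", 17), ("R", 18)]
        receptor = CoarseStructure(beads=beads, coords=np.array(coords))
        ligand = CoarseStructure(beads=[("L", 1)], coords=np.array([[0.0, 0, 0]]))
        restraints = [
            DistanceRestraint(anchor_a=("R", 17), anchor_b=("L", 1), lower=0.0, upper=40.0),
            DistanceRestraint(anchor_a=("R", 18), anchor_b=("L", 1), lower=0.0, upper=40.0),
            DistanceRestraint(
                anchor_a=("R", 18), anchor_b=("L", 1), lower=0.0, upper=9.0, source="TAIL"
            ),
        ]
        params = {"grid_spacing": 2.0, "padding": 8.0, "n_rotations": 1,
                  "clash_dist": 3.0, "canonicalize": False}
        truth = {"tail_restraint_index": 2}
    elif scenario == "symmetric":
        receptor = CoarseStructure(
            beads=[("R", 1), ("R", 2)], coords=np.array([[-2.0, 0, 0], [2.0, 0, 0]])
        )
        ligand = CoarseStructure(beads=[("L", 1)], coords=np.array([[0.0, 0, 0]]))
        restraints = [
            DistanceRestraint(anchor_a=("R", 1), anchor_b=("L", 1), lower=0.0, upper=10.0),
            DistanceRestraint(anchor_a=("R", 2), anchor_b=("L", 1), lower=0.0, upper=10.0),
        ]
        params = {"grid_spacing": 2.0, "padding": 10.0, "n_rotations": 1,
                  "clash_dist": 3.0, "canonicalize": False, "contact_dist": 6.0}
        truth = {}
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    census = _brute_force_census(receptor, ligand, restraints, params)
    return ToyScenario(
        receptor=receptor,
        ligand=ligand,
        restraints=restraints,
        scan_params=params,
        census=census,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# energy trajectories and decomposition tables
# ---------------------------------------------------------------------------

def gen_energy(
    seed: int,
    plateau: float = -45.0,
    transient: float = 15.0,
    tau_ps: float = 1500.0,
    noise_sd: float = 2.0,
    duration_ps: float = 20000.0,
    interval_ps: float = 10.0,
    group_id: str = "group1",
) -> tuple[EnergyTrajectory, dict]:
    """ΔG_eff series: plateau + decaying equilibration transient + noise.

    Defaults emulate a 20 ns production run sampled every 10 ps (2000
    frames) that starts ~15 kcal/mol above a −45 kcal/mol plateau and
    relaxes with a 1.5 ns time constant under 2 kcal/mol Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_ps / interval_ps))
    times = interval_ps * np.arange(1, n + 1)
    values = plateau + transient * np.exp(-times / tau_ps) + rng.normal(0, noise_sd, n)
    traj = EnergyTrajectory(times=times, dg_eff=values, group_id=group_id)
    truth = {
        "plateau": plateau,
        "transient": transient,
        "tau_ps": tau_ps,
        "noise_sd": noise_sd,
        "n_frames": n,
    }
    return traj, truth


def gen_energy_groups(
    seed: int,
    plateaus: dict[str, float] | None = None,
    **kwargs,
) -> tuple[list[EnergyTrajectory], dict]:
    """Several trajectories with distinct plateaus; truth marks the lowest."""
    plateaus = plateaus or {"group1": -35.0, "group2": -45.0, "group3": -38.0}
    rng = np.random.default_rng(seed)
    trajs = []
    for gid in sorted(plateaus):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        traj, _ = gen_energy(sub_seed, plateau=plateaus[gid], group_id=gid, **kwargs)
        trajs.append(traj)
    truth = {"plateaus": plateaus, "lowest": min(plateaus, key=lambda g: plateaus[g])}
    return trajs, truth


def gen_decomposition(
    seed: int,
    n_residues: int = 40,
    n_hotspots: int = 6,
    hotspot_range: tuple[float, float] = (-3.0, -1.2),
    background_range: tuple[float, float] = (-0.6, 0.3),
) -> tuple[DecompositionTable, dict]:
    """Per-residue decomposition with planted hot-spots below −1.0 kcal/mol.

    Hot-spot side-chain contributions are drawn strictly below the calling
    threshold and background residues strictly above it, so the planted set
    is recovered exactly.
    """
    rng = np.random.default_rng(seed)
    ids = [f"RES{i + 1}" for i in range(n_residues)]
    hot_idx = sorted(rng.choice(n_residues, size=n_hotspots, replace=False))
    dg_sc = rng.uniform(*background_range, size=n_residues)
    for i in hot_idx:
        dg_sc[i] = rng.uniform(*hotspot_range)
    table = DecompositionTable(
        table=pd.DataFrame(
            {
                "residue_id": ids,
                "chain": "R",
                "dg_sidechain": np.round(dg_sc, 4),
                "dg_backbone": np.round(rng.uniform(-0.5, 0.5, size=n_residues), 4),
            }
        )
    )
    truth = {"hotspots": [ids[i] for i in hot_idx]}
    return table, truth


def gen_cas_pair(
    seed: int,
    ddg_true: float = 2.5,
    base_mean: float = -45.0,
    noise_sd: float = 2.0,
    n_frames: int = 1000,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Paired wild-type/mutant post-equilibration series with planted ΔΔG."""
    rng = np.random.default_rng(seed)
    wt = base_mean + rng.normal(0, noise_sd, n_frames)
    mut = base_mean + ddg_true + rng.normal(0, noise_sd, n_frames)
    return wt, mut, {"ddg": ddg_true, "noise_sd": noise_sd, "n_frames": n_frames}
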