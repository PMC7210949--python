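"""MM-GBSA post-processing: effective-energy trajectories, prEFED, CAS.

Consumes per-frame effective binding free energies (ΔG_eff, kcal/mol) and
per-residue decomposition tables as produced by MMPBSA-style tools; the
energy evaluation itself is out of scope. Provides accumulated means,
equilibration-window statistics, group selection by lowest equilibrated
mean, hot-spot calling on side-chain contributions (threshold −1.0
kcal/mol), and computational-alanine-scanning ΔΔG with propagated SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EnergyTrajectory:
    """Uniformly sampled per-frame ΔG_eff series (times in ps)."""

    times: np.ndarray
    dg_eff: np.ndarray
    group_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.dg_eff = np.asarray(self.dg_eff, dtype=float)
        if len(self.times) != len(self.dg_eff):
            raise ValueError("times and dg_eff must have equal length")
        if len(self.times) == 0:
            raise ValueError("empty trajectory")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.any(np.abs(dt - dt[0]) > 1e-9 * max(abs(dt[0]), 1.0)):
                raise ValueError("frame spacing must be uniform")


@dataclass
class DecompositionTable:
    """Per-residue side-chain/backbone energy contributions (kcal/mol)."""

    table: pd.DataFrame  # columns: residue_id, chain, dg_sidechain, dg_backbone

    def __post_init__(self) -> None:
        required = {"residue_id", "dg_sidechain"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"decomposition table missing columns {sorted(missing)}")
        if self.table["residue_id"].duplicated().any():
            raise ValueError("residue ids must be unique")


@dataclass
class CASEntry:
    """Alanine-scan result: ΔΔG = ΔG(mutant) − ΔG(wild-type) with SEM."""

    residue_id: str
    ddg: float
    sem: float

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


def sample_count(duration_ps: float, interval_ps: float) -> int:
    """Number of frames when sampling every ``interval_ps`` over ``duration_ps``.

    The interval must divide the duration (tolerance 1e-9); e.g. a 20,000 ps
    production window sampled every 10 ps yields 2000 values.
    """
    if interval_ps <= 0 or duration_ps <= 0:
        raise ValueError("duration and interval must be positive")
    ratio = duration_ps / interval_ps
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"interval {interval_ps} ps does not divide duration {duration_ps} ps")
    return int(round(ratio))


def accumulated_mean(traj: EnergyTrajectory) -> np.ndarray:
    """Running mean: out[i] = mean(dg_eff[0..i])."""
    values = traj.dg_eff
    return np.cumsum(values) / np.arange(1, len(values) + 1)


def _sem_independent(values: np.ndarray) -> float:
    n = len(values)
    if n < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(n))


def _sem_block(values: np.ndarray, n_blocks: int = 10) -> float:
    """Block-averaging SEM — an honest alternative when frames are correlated."""
    n = len(values)
    n_blocks = min(n_blocks, n)
    if n_blocks < 2:
        return 0.0
    blocks = np.array_split(values, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(np.std(means, ddof=1) / np.sqrt(len(means)))


def equilibrated_stats(
    traj: EnergyTrajectory, t_eq_ps: float, sem_method: str = "independent"
) -> tuple[float, float, int]:
    """Mean, SEM and frame count over the window time >= t_eq (inclusive).

    ``sem_method='independent'`` treats frames as uncorrelated;
    ``'block'`` uses block averaging.
    """
    mask = traj.times >= t_eq_ps
    if not mask.any():
        raise ValueError(f"t_eq={t_eq_ps} ps leaves no frames")
    window = traj.dg_eff[mask]
    if sem_method == "independent":
        sem = _sem_independent(window)
    elif sem_method == "block":
        sem = _sem_block(window)
    else:
        raise ValueError(f"unknown sem_method {sem_method!r}")
    return float(window.mean()), sem, int(mask.sum())


def select_group(trajs: list[EnergyTrajectory], t_eq_ps: float) -> str:
    """Group with the lowest (most favourable) equilibrated mean ΔG_eff.

    Ties are broken by group_id order, with a warning.
    """
    import warnings

    if len(trajs) < 2:
        raise ValueError("group selection needs at least 2 trajectories")
    means = {t.group_id: equilibrated_stats(t, t_eq_ps)[0] for t in trajs}
    best_value = min(means.values())
    winners = sorted(g for g, m in means.items() if m == best_value)
    if len(winners) > 1:
        warnings.warn(f"tied equilibrated means among {winners}; using {winners[0]}", stacklevel=2)
    return winners[0]


def call_hotspots(table: DecompositionTable, threshold: float = -1.0) -> list[str]:
    """Residues whose side-chain contribution is at most ``threshold`` kcal/mol.

    The boundary is inclusive: exactly −1.0 kcal/mol is a hot-spot. Output is
    sorted by energy ascending (strongest contributors first).
    """
    df = table.table
    hits = df[df["dg_sidechain"] <= threshold].sort_values("dg_sidechain")
    return [str(r) for r in hits["residue_id"]]


def cas_ddg(
    residue_id: str,
    wt: np.ndarray,
    mut: np.ndarray,
    sem_method: str = "independent",
) -> CASEntry:
    """Alanine-scan ΔΔG from post-equilibration wild-type and mutant series.

    ΔΔG = mean(mut) − mean(wt); the SEM is propagated in quadrature from the
    two series.
    """
    wt = np.asarray(wt, dtype=float)
    mut = np.asarray(mut, dtype=float)
    if len(wt) == 0 or len(mut) == 0:
        raise ValueError("empty energy series")
    sem_fn = _sem_independent if sem_method == "independent" else _sem_block
    sem = float(np.hypot(sem_fn(wt), sem_fn(mut)))
    return CASEntry(residue_id=residue_id, ddg=float(mut.mean() - wt.mean()), sem=sem)


def read_energy_csv(path, group_id: str = "") -> EnergyTrajectory:
    """Read a (time_ps, dg_eff) CSV into an :class:`EnergyTrajectory`."""
    df = pd.read_csv(path)
    for col in ("time_ps", "dg_eff"):
        if col not in df.columns:
            raise ValueError(f"energy table {path} missing column {col!r}")
    return EnergyTrajectory(
        times=df["time_ps"].to_numpy(), dg_eff=df["dg_eff"].to_numpy(), group_id=group_id
    )


def read_decomposition_csv(path) -> DecompositionTable:
    """Read a per-residue decomposition CSV (MMPBSA-output-like columns)."""
    return DecompositionTable(table=pd.read_csv(path))
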