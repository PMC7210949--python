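"""Saturation radioligand binding: one-site total + nonspecific model.

Total binding at free ligand concentration x (nM) is modelled as

    B_total(x) = Bmax · x / (Kd + x) + NS · x

with Bmax the specific-site capacity (counts), Kd the dissociation constant
(nM) and NS a linear nonspecific slope (counts per nM). Free ligand is
approximated by added ligand (no depletion correction), as in the assay the
model describes. Fits run on raw counts; curve normalization is
presentation-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize


@dataclass
class BindingDataset:
    """Concentration series with total and nonspecific replicate counts.

    ``total_counts`` and ``nonspecific_counts`` are (n_conc, n_rep) arrays.
    Concentrations are strictly positive and sorted ascending.
    """

    ligand_nM: np.ndarray
    total_counts: np.ndarray
    nonspecific_counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ligand_nM = np.asarray(self.ligand_nM, dtype=float)
        self.total_counts = np.atleast_2d(np.asarray(self.total_counts, dtype=float))
        self.nonspecific_counts = np.atleast_2d(
            np.asarray(self.nonspecific_counts, dtype=float)
        )
        if np.any(self.ligand_nM <= 0):
            raise ValueError("ligand concentrations must be strictly positive")
        if np.any(np.diff(self.ligand_nM) <= 0):
            raise ValueError("ligand concentrations must be sorted strictly ascending")
        if len(np.unique(self.ligand_nM)) < 5:
            raise ValueError("need at least 5 distinct concentrations for fitting")
        for name, arr in (("total", self.total_counts), ("nonspecific", self.nonspecific_counts)):
            if arr.shape[0] != len(self.ligand_nM):
                raise ValueError(f"{name} counts rows must match concentration count")
            if np.any(arr < 0):
                raise ValueError(f"{name} counts must be non-negative")


@dataclass
class BindingFit:
    kd_nM: float
    bmax: float
    ns_slope: float
    se_kd: float
    converged: bool
    residual_ss: float
    mode: str = "joint"


def model_total(x, kd: float, bmax: float, ns: float):
    """One-site total binding: Bmax·x/(Kd+x) + NS·x."""
    if kd < 0 or bmax < 0 or ns < 0:
        raise ValueError("model parameters must be non-negative")
    x = np.asarray(x, dtype=float)
    return bmax * x / (kd + x) + ns * x


def normalize_relative(curve) -> np.ndarray:
    """Scale a specific-binding curve to its maximum (max maps to exactly 1)."""
    curve = np.asarray(curve, dtype=float)
    top = curve.max()
    if top <= 0:
        raise ValueError("cannot normalize a curve with no positive value")
    return curve / top


def _initial_guess(x: np.ndarray, y_mean: np.ndarray) -> tuple[float, float, float]:
    """Deterministic initialization from the data.

    NS slope from the two largest concentrations (their incremental slope is
    dominated by the linear term once the site saturates); Kd from the
    concentration nearest half the maximal specific signal; Bmax from the
    maximal specific signal.
    """
    ns0 = max((y_mean[-1] - y_mean[-2]) / (x[-1] - x[-2]), 0.0)
    specific = np.clip(y_mean - ns0 * x, 0.0, None)
    top = specific.max()
    if top <= 0:
        return float(np.median(x)), float(max(y_mean.max(), 1e-9)), ns0
    kd0 = float(x[np.argmin(np.abs(specific - top / 2))])
    return max(kd0, x[0]), float(top), ns0


def fit_one_site(ds: BindingDataset, mode: str = "joint") -> BindingFit:
    """Nonlinear least-squares fit of the one-site total+nonspecific model.

    ``mode='joint'`` co-fits Kd, Bmax and NS on the total counts;
    ``mode='pinned-ns'`` first pins NS by a through-origin linear fit to the
    nonspecific control counts, then fits Kd and Bmax only. The Kd standard
    error comes from the Jacobian-based covariance. Non-convergence is
    reported through ``converged=False`` (last iterate returned), never as an
    exception.
    """
    if mode not in ("joint", "pinned-ns"):
        raise ValueError(f"unknown mode {mode!r}")
    x = ds.ligand_nM
    n_rep = ds.total_counts.shape[1]
    x_flat = np.repeat(x, n_rep)
    y_flat = ds.total_counts.ravel()
    y_mean = ds.total_counts.mean(axis=1)
    kd0, bmax0, ns0 = _initial_guess(x, y_mean)

    if mode == "pinned-ns":
        xs = np.repeat(x, ds.nonspecific_counts.shape[1])
        ys = ds.nonspecific_counts.ravel()
        ns_pinned = float(np.sum(xs * ys) / np.sum(xs * xs))  # through origin

        def fun(xv, kd, bmax):
            return bmax * xv / (kd + xv) + ns_pinned * xv

        p0 = [kd0, bmax0]
        bounds = ([1e-12, 1e-12], [np.inf, np.inf])
    else:

        def fun(xv, kd, bmax, ns):
            return bmax * xv / (kd + xv) + ns * xv

        p0 = [kd0, bmax0, ns0]
        bounds = ([1e-12, 1e-12, 0.0], [np.inf, np.inf, np.inf])

    try:
        popt, pcov = optimize.curve_fit(
            fun, x_flat, y_flat, p0=p0, bounds=bounds, maxfev=20000
        )
        converged = True
    except RuntimeError:
        # keep the best iterate via a bounded least_squares restart
        res = optimize.least_squares(
            lambda p: fun(x_flat, *p) - y_flat, p0, bounds=bounds, max_nfev=2000
        )
        popt = res.x
        pcov = np.full((len(p0), len(p0)), np.nan)
        converged = False

    resid = fun(x_flat, *popt) - y_flat
    se_kd = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else float("nan")
    if mode == "pinned-ns":
        kd, bmax = popt
        ns = ns_pinned
    else:
        kd, bmax, ns = popt
    return BindingFit(
        kd_nM=float(kd),
        bmax=float(bmax),
        ns_slope=float(ns),
        se_kd=se_kd,
        converged=converged,
        residual_ss=float(np.sum(resid**2)),
        mode=mode,
    )


def specific_binding(ds: BindingDataset, fit: BindingFit) -> np.ndarray:
    """Mean total counts minus the fitted nonspecific component, per concentration."""
    return ds.total_counts.mean(axis=1) - fit.ns_slope * ds.ligand_nM
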