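"""Hydrodynamics: SEC calibration and Stokes-radius fold classification.

A size-exclusion column is calibrated with globular standards by regressing
log10(Rs) on elution volume (the Laurent–Killander style linearization);
measured Stokes radii are then compared against theoretical power laws
log10(Rs) = a + b·log10(M) for four conformational classes — natively folded
(NF), molten globule (MG), premolten globule (PMG) and intrinsically
disordered (IDP) — each with a ±10% outer band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats

FOLD_CLASSES = ("NF", "MG", "PMG", "IDP")


@dataclass
class SECStandard:
    """A gel-filtration standard: known Stokes radius (Å) and elution volume (mL)."""

    name: str
    stokes_radius: float
    elution_volume: float

    def __post_init__(self) -> None:
        if self.stokes_radius <= 0 or self.elution_volume <= 0:
            raise ValueError(f"{self.name}: radius and volume must be positive")


@dataclass
class SECCalibration:
    """Fitted line log10(Rs/Å) = slope·V + intercept with its R²."""

    slope: float
    intercept: float
    r_squared: float
    n_standards: int

    def stokes_from_elution(self, elution_volume: float) -> float:
        """Stokes radius (Å) predicted for an elution volume (mL)."""
        return float(10 ** (self.slope * elution_volume + self.intercept))


def calibrate_sec(standards: list[SECStandard]) -> SECCalibration:
    """Least-squares calibration of log10(Rs) against elution volume.

    Requires at least three standards with distinct volumes. Larger particles
    elute earlier, so a sensible calibration has a negative slope; a
    non-negative slope is allowed but indicates inverted input.
    """
    if len(standards) < 3:
        raise ValueError("SEC calibration needs at least 3 standards")
    volumes = np.array([s.elution_volume for s in standards])
    log_rs = np.log10([s.stokes_radius for s in standards])
    if np.allclose(volumes, volumes[0]):
        raise ValueError("degenerate calibration: all elution volumes identical")
    fit = stats.linregress(volumes, log_rs)
    return SECCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_standards=len(standards),
    )


@dataclass
class FoldClassBands:
    """Power-law coefficients per fold class with a fractional band tolerance.

    ``coefficients[cls] = (a, b)`` such that Rs = 10^(a + b·log10 M) with Rs
    in Å and M in Da. The band of a class at mass M is
    [Rs·(1−tolerance), Rs·(1+tolerance)].
    """

    coefficients: dict[str, tuple[float, float]]
    tolerance: float = 0.10

    def __post_init__(self) -> None:
        missing = set(FOLD_CLASSES) - set(self.coefficients)
        if missing:
            raise ValueError(f"missing fold classes {sorted(missing)}")
        if not (0 < self.tolerance < 1):
            raise ValueError("tolerance must be a fraction in (0, 1)")
        for cls, (_, b) in self.coefficients.items():
            if not (0.3 <= b <= 0.6):
                raise ValueError(f"{cls}: exponent b={b} outside the plausible 0.3–0.6 range")


def load_fold_bands(
    variant: str = "default",
    tolerance: float = 0.10,
    path: str | Path | None = None,
) -> FoldClassBands:
    """Load the shipped Stokes-radius power-law coefficient sets.

    ``variant`` selects the IDP calibration: ``default`` (natively unfolded
    coil-like), ``urea_unfolded`` or ``gdmcl_unfolded``.
    """
    if path is None:
        text = resources.files("coreceptor.data").joinpath("stokes_laws.json").read_text()
    else:
        text = Path(path).read_text()
    data = json.loads(text)
    if variant not in data["sets"]:
        raise ValueError(f"unknown coefficient set {variant!r}; have {sorted(data['sets'])}")
    coeffs = {
        cls: (entry["a"], entry["b"]) for cls, entry in data["sets"][variant].items()
    }
    return FoldClassBands(coefficients=coeffs, tolerance=tolerance)


def theoretical_rs(mass_da: float, cls: str, bands: FoldClassBands) -> float:
    """Theoretical Stokes radius (Å) of a chain of mass ``mass_da`` in class ``cls``."""
    if mass_da <= 0:
        raise ValueError("mass must be positive")
    if cls not in bands.coefficients:
        raise ValueError(f"unknown fold class {cls!r}")
    a, b = bands.coefficients[cls]
    return float(10 ** (a + b * np.log10(mass_da)))


@dataclass
class FoldAssignment:
    fold_class: str
    margin: float  # |measured − theoretical| / theoretical of the assigned class
    inside_band: bool


def classify_fold(rs_measured: float, mass_da: float, bands: FoldClassBands) -> FoldAssignment:
    """Assign a measured Stokes radius to the fold class whose band contains it.

    Each class band is the theoretical radius ± the fractional tolerance
    (default 10%, the conventional outer limit). If several bands contain the
    measurement the nearest band center wins; if none does, the nearest class
    is returned flagged as outside all bands.
    """
    if rs_measured <= 0:
        raise ValueError("measured radius must be positive")
    margins = {}
    containing = []
    for cls in FOLD_CLASSES:
        rs_theo = theoretical_rs(mass_da, cls, bands)
        rel = abs(rs_measured - rs_theo) / rs_theo
        margins[cls] = rel
        if rs_theo * (1 - bands.tolerance) <= rs_measured <= rs_theo * (1 + bands.tolerance):
            containing.append(cls)
    pool = containing if containing else list(FOLD_CLASSES)
    best = min(pool, key=lambda c: margins[c])
    return FoldAssignment(
        fold_class=best, margin=margins[best], inside_band=bool(containing)
    )
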