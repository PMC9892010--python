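"""Slice-number to apparent-molecular-mass calibration for blue native gels.

Marker complexes with predicted native masses and sharply focused profile
peaks anchor the relationship between gel slice number and log10 apparent
mass.  The relationship is fitted with a generalized logistic (Richards)
sigmoid, which contains the symmetric 4-parameter logistic as the special
case ``g = 1`` but tolerates the asymmetry real marker sets show: migration
of very large assemblies (and anomalously migrating particles such as
ribosomal subunits) compresses the top of the gel.

The builtin marker table covers 77 kDa to 3,020 kDa over 245 slices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class CalibrationMarker:
    """One marker complex: predicted mass and the slice of its profile maximum."""

    name: str
    predicted_mass_kda: float
    slice_max: float
    log_mass: float | None = None

    #: Published marker tables print log masses to 2 decimals, sometimes
    #: truncated rather than rounded (e.g. 77 kDa -> 1.88, not 1.89), so the
    #: consistency band must admit a full last-digit truncation error.
    LOG_MASS_TOLERANCE = 0.008

    def __post_init__(self) -> None:
        lm = math.log10(self.predicted_mass_kda)
        if self.log_mass is None:
            object.__setattr__(self, "log_mass", round(lm, 2))
        elif abs(self.log_mass - lm) > self.LOG_MASS_TOLERANCE:
            raise ValueError(
                f"marker '{self.name}': log_mass {self.log_mass} inconsistent with "
                f"mass {self.predicted_mass_kda} kDa (log10 = {lm:.3f})"
            )


#: Marker complexes of the reference yeast mitochondrial dataset
#: (name; predicted mass kDa; slice of peak maximum).
BUILTIN_MARKERS: tuple[CalibrationMarker, ...] = (
    CalibrationMarker("oxoglutarate dehydrogenase complex", 3020.0, 21.4, 3.48),
    CalibrationMarker("pre-60S ribosome large subunit", 2680.0, 11.5, 3.43),
    CalibrationMarker("F1Fo-ATP synthase dimer", 1250.0, 54.1, 3.10),
    CalibrationMarker("respiratory III2IV2 supercomplex", 1000.0, 62.4, 3.00),
    CalibrationMarker("respiratory III2IV1 supercomplex", 750.0, 71.6, 2.88),
    CalibrationMarker("F1Fo-ATP synthase monomer", 600.0, 85.6, 2.78),
    CalibrationMarker("SAM-Mdm10 complex", 185.5, 143.8, 2.27),
    CalibrationMarker("TIM22 complex", 174.0, 136.2, 2.24),
    CalibrationMarker("ATM1 transporter", 155.0, 157.0, 2.19),
    CalibrationMarker("SAM core complex", 129.4, 173.5, 2.11),
    CalibrationMarker("succinate dehydrogenase (complex II)", 130.0, 182.0, 2.11),
    CalibrationMarker("NADP-cytochrome P450 reductase", 77.0, 239.0, 1.88),
)

MIN_MARKERS = 5


def load_markers(source: str | Path = "builtin") -> list[CalibrationMarker]:
    """Load calibration markers from a TSV file, or the builtin table.

    The TSV needs columns ``name``, ``mass_kda`` and ``slice_max``; an
    optional ``log_mass`` column is cross-checked against ``mass_kda``.
    """
    if source == "builtin":
        return list(BUILTIN_MARKERS)
    df = pd.read_csv(source, sep="\t")
    for col in ("name", "mass_kda", "slice_max"):
        if col not in df.columns:
            raise ValueError(f"{source}: missing marker column '{col}'")
    markers = [
        CalibrationMarker(
            str(r["name"]),
            float(r["mass_kda"]),
            float(r["slice_max"]),
            float(r["log_mass"]) if "log_mass" in df.columns else None,
        )
        for _, r in df.iterrows()
    ]
    if len(markers) < MIN_MARKERS:
        raise ValueError(
            f"need at least {MIN_MARKERS} markers to fit a calibration, got {len(markers)}"
        )
    return markers


def _richards(x: np.ndarray, lo: float, hi: float, x0: float, b: float, g: float):
    """Decreasing generalized logistic in (slice, log10 mass) space."""
    return lo + (hi - lo) / (1.0 + np.exp((x - x0) / b)) ** g


@dataclass
class MassCalibration:
    """Fitted sigmoid mapping slice index <-> log10 apparent mass (kDa).

    ``params`` are (lower asymptote, upper asymptote, midpoint slice,
    slope width in slices, asymmetry exponent).  ``valid_range`` is the
    slice interval spanned by the markers; conversions outside it are
    extrapolations and are flagged, not refused, because genuine profile
    peaks can sit beyond the gel ends.
    """

    params: tuple[float, float, float, float, float]
    fit_residuals: np.ndarray
    valid_range: tuple[float, float]
    n_slices: int = 245

    @property
    def max_abs_residual(self) -> float:
        return float(np.max(np.abs(self.fit_residuals)))

    def log_mass_at(self, slice_index: float | np.ndarray) -> np.ndarray:
        return _richards(np.asarray(slice_index, dtype=float), *self.params)

    def is_extrapolated(self, slice_index: float | np.ndarray) -> np.ndarray:
        s = np.asarray(slice_index, dtype=float)
        return (s < self.valid_range[0]) | (s > self.valid_range[1])

    def slice_to_mass(self, slice_index: float | np.ndarray):
        """Apparent mass in kDa at a (real-valued) slice position.

        Returns ``(mass_kda, extrapolated_flag)``; scalar in, scalar out.
        """
        mass = 10.0 ** self.log_mass_at(slice_index)
        flag = self.is_extrapolated(slice_index)
        if np.isscalar(slice_index) or np.ndim(slice_index) == 0:
            return float(mass), bool(flag)
        return mass, flag

    def mass_to_slice(self, mass_kda: float | np.ndarray):
        """Analytic inverse: slice position at which a complex of this mass runs."""
        lo, hi, x0, b, g = self.params
        y = np.log10(np.asarray(mass_kda, dtype=float))
        if np.any(y <= lo) or np.any(y >= hi):
            raise ValueError(
                f"mass outside calibration range "
                f"({10 ** lo:.1f}..{10 ** hi:.1f} kDa asymptotes)"
            )
        s = x0 + b * np.log(((hi - lo) / (y - lo)) ** (1.0 / g) - 1.0)
        if np.ndim(mass_kda) == 0:
            return float(s)
        return s


def fit_calibration(
    markers: list[CalibrationMarker] | None = None, n_slices: int = 245
) -> MassCalibration:
    """Least-squares fit of the sigmoid to marker (slice, log10 mass) points.

    The asymmetry exponent is bounded in [0.05, 20] and the slope width at
    >= 3 slices; unbounded, the Richards family can collapse onto a step
    function when a single out-of-order marker dominates.  The accepted fit
    is checked to be strictly decreasing over the whole gel.
    """
    if markers is None:
        markers = list(BUILTIN_MARKERS)
    if len(markers) < MIN_MARKERS:
        raise ValueError(
            f"need at least {MIN_MARKERS} markers to fit a calibration, got {len(markers)}"
        )
    s = np.array([m.slice_max for m in markers], dtype=float)
    if len(np.unique(s)) != len(s):
        raise ValueError("marker slice_max values must be distinct")
    y = np.array([math.log10(m.predicted_mass_kda) for m in markers], dtype=float)

    p0 = [y.min() - 0.3, y.max() + 0.3, float(np.median(s)), 50.0, 0.5]
    lower = [y.min() - 2.0, y.min(), 1.0, 3.0, 0.05]
    upper = [y.max(), y.max() + 2.0, float(n_slices), 4.0 * n_slices, 20.0]
    p0 = np.clip(p0, lower, upper)
    try:
        params, _ = curve_fit(
            _richards, s, y, p0=p0, bounds=(lower, upper), maxfev=200000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"calibration fit did not converge (initial guess {p0}, "
            f"marker residuals at p0 = {y - _richards(s, *p0)})"
        ) from exc

    residuals = y - _richards(s, *params)
    grid = np.linspace(1, n_slices, 4 * n_slices)
    if not np.all(np.diff(_richards(grid, *params)) < 0):
        raise RuntimeError("fitted calibration curve is not strictly decreasing")
    return MassCalibration(
        params=tuple(float(p) for p in params),
        fit_residuals=residuals,
        valid_range=(float(s.min()), float(s.max())),
        n_slices=n_slices,
    )


def save_calibration(cal: MassCalibration, path: str | Path) -> None:
    """Persist the fitted parameters and residuals as key-value text."""
    lines = [
        f"lower_asymptote\t{cal.params[0]!r}",
        f"upper_asymptote\t{cal.params[1]!r}",
        f"midpoint_slice\t{cal.params[2]!r}",
        f"slope_width\t{cal.params[3]!r}",
        f"asymmetry\t{cal.params[4]!r}",
        f"valid_range\t{cal.valid_range[0]!r}\t{cal.valid_range[1]!r}",
        f"n_slices\t{cal.n_slices}",
        "residuals\t" + "\t".join(repr(float(r)) for r in cal.fit_residuals),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_calibration(path: str | Path) -> MassCalibration:
    fields: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        key, *vals = line.split("\t")
        fields[key] = vals
    params = tuple(
        float(fields[k][0])
        for k in ("lower_asymptote", "upper_asymptote", "midpoint_slice", "slope_width", "asymmetry")
    )
    return MassCalibration(
        params=params,  # type: ignore[arg-type]
        fit_residuals=np.array([float(v) for v in fields["residuals"]]),
        valid_range=(float(fields["valid_range"][0]), float(fields["valid_range"][1])),
        n_slices=int(fields["n_slices"][0]),
    )
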