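"""Ligand-binding titration analysis: 1:1 binding fits, competition
conversion, normalization and fold-change comparison.

Terbium luminescence titrations are normalized to bound fractions and fit
to a one-site model by non-linear least squares.  Two model variants are
supported: the hyperbolic form f = L/(K_d + L) (free-ligand approximation)
and the depletion-corrected form
f = ((P + L + K_d) - sqrt((P + L + K_d)^2 - 4 P L)) / (2 P),
relevant whenever the protein concentration P is comparable to K_d.
A competitor's true dissociation constant follows from its apparent one via
K_d = K_app / (1 + [probe]/K_d(probe)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TitrationSeries", "BindingFit", "normalize_series", "fit_one_site",
    "competition_kd", "apparent_kd", "fold_change", "read_titration_csv",
]

_UNIT_FACTORS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9}


@dataclass
class TitrationSeries:
    """Concentration-response data (molar / relative fluorescence units)."""

    concentrations: np.ndarray
    intensities: np.ndarray
    replicates: np.ndarray | None = None
    protein_conc: float | None = None
    normalized: bool = False

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.replicates is not None:
            self.replicates = np.asarray(self.replicates)
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if len(self.concentrations) != len(self.intensities):
            raise ValueError("concentration/intensity length mismatch")
        for rep in self.replicate_ids():
            c = self.concentrations[self._mask(rep)]
            if np.any(np.diff(c) <= 0):
                raise ValueError("concentrations must be strictly increasing "
                                 "within each replicate")

    def _mask(self, rep) -> np.ndarray:
        if self.replicates is None:
            return np.ones(len(self.concentrations), dtype=bool)
        return self.replicates == rep

    def replicate_ids(self) -> list:
        if self.replicates is None:
            return [0]
        return sorted(set(self.replicates.tolist()))

    def means(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(unique concentrations, mean intensity, standard deviation)."""
        conc = np.unique(self.concentrations)
        mean = np.empty(len(conc))
        sd = np.empty(len(conc))
        for k, c in enumerate(conc):
            vals = self.intensities[self.concentrations == c]
            mean[k] = vals.mean()
            sd[k] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        return conc, mean, sd


@dataclass
class BindingFit:
    k_d: float
    amplitude: float
    baseline: float
    rss: float
    variant: str
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.k_d <= 0:
            raise ValueError("fitted K_d must be positive")


def _hyperbolic(conc: np.ndarray, k_d: float) -> np.ndarray:
    return conc / (k_d + conc)


def _depletion(conc: np.ndarray, k_d: float, protein: float) -> np.ndarray:
    s = protein + conc + k_d
    return (s - np.sqrt(s ** 2 - 4.0 * protein * conc)) / (2.0 * protein)


def normalize_series(series: TitrationSeries, mode: str = "plateau"
                     ) -> TitrationSeries:
    """Map replicate-mean intensities to bound fractions in [0, 1].

    'minmax' scales between the observed minimum and maximum; 'plateau'
    (default) fits a hyperbola with free baseline/plateau to the means and
    scales so the fitted plateau maps to 1, which is robust when the curve
    does not fully saturate.
    """
    conc, mean, _ = series.means()
    if np.ptp(mean) == 0:
        raise ValueError("cannot normalize a constant intensity series")
    if mode == "minmax":
        lo, hi = mean.min(), mean.max()
    elif mode == "plateau":
        def resid(p):
            k_d, amp, base = p
            return base + amp * _hyperbolic(conc, k_d) - mean

        span = mean.max() - mean.min()
        pos = conc[conc > 0]
        x0 = [np.median(pos) if len(pos) else 1.0, span, mean.min()]
        sol = least_squares(resid, x0,
                            bounds=([1e-12, 0.0, -np.inf], [np.inf] * 3))
        lo, hi = sol.x[2], sol.x[2] + sol.x[1]
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    frac = (mean - lo) / (hi - lo)
    return TitrationSeries(conc, frac, None, series.protein_conc, normalized=True)


def fit_one_site(series: TitrationSeries, variant: str = "hyperbolic",
                 protein_conc: float | None = None) -> BindingFit:
    """Fit a 1:1 binding model to a (normalized) titration.

    ``variant``: 'hyperbolic' or 'depletion' (requires the protein
    concentration).  Bounded least squares with a positivity constraint on
    K_d, multi-started from the low, geometric-mean and high ends of the
    concentration range.  Emits a warning when fitting the hyperbolic model
    in a depletion-prone regime (P/K_d > 0.5).
    """
    if not series.normalized:
        series = normalize_series(series)
    conc, frac, _ = series.means() if series.replicates is not None \
        else (series.concentrations, series.intensities, None)
    if len(conc) < 4:
        raise ValueError("need at least 4 points to fit")
    protein = protein_conc if protein_conc is not None else series.protein_conc
    if variant == "depletion" and not protein:
        raise ValueError("depletion-corrected fit needs the protein concentration")

    def model(p):
        k_d, amp, base = p
        if variant == "hyperbolic":
            return base + amp * _hyperbolic(conc, k_d)
        return base + amp * _depletion(conc, k_d, protein)

    pos = conc[conc > 0]
    geo = float(np.exp(np.mean(np.log(pos)))) if len(pos) else 1.0
    best = None
    for k0 in (pos.min() if len(pos) else 1e-6, geo, pos.max() if len(pos) else 1.0):
        sol = least_squares(lambda p: model(p) - frac,
                            [k0, 1.0, 0.0],
                            bounds=([1e-15, 1e-6, -0.5], [np.inf, 10.0, 0.5]))
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    rss, sol = best
    if not sol.success and rss > 1e-6 * len(conc):
        raise RuntimeError(f"one-site fit did not converge: {sol.message}")
    notes = []
    if variant == "hyperbolic" and protein and protein / sol.x[0] > 0.5:
        msg = (f"protein concentration ({protein:.3g} M) is comparable to the "
               f"fitted K_d ({sol.x[0]:.3g} M); the hyperbolic model will bias "
               f"K_d high — consider the depletion-corrected variant")
        warnings.warn(msg)
        notes.append(msg)
    return BindingFit(float(sol.x[0]), float(sol.x[1]), float(sol.x[2]),
                      rss, variant, notes)


def fit_both_variants(series: TitrationSeries,
                      protein_conc: float | None = None) -> dict[str, BindingFit]:
    """Hyperbolic fit, plus the depletion-corrected fit whenever the protein
    concentration is known and non-negligible (P >= K_d/10)."""
    out = {"hyperbolic": fit_one_site(series, "hyperbolic", protein_conc)}
    protein = protein_conc if protein_conc is not None else series.protein_conc
    if protein and protein >= out["hyperbolic"].k_d / 10.0:
        out["depletion"] = fit_one_site(series, "depletion", protein_conc)
    return out


def competition_kd(k_app: float, competitor_conc: float,
                   k_d_competitor: float) -> float:
    """True K_d of a competing ligand from its apparent K_d:
    K_d = K_app / (1 + [probe]/K_d(probe))."""
    if k_app <= 0 or k_d_competitor <= 0 or competitor_conc < 0:
        raise ValueError("concentrations and constants must be positive")
    return k_app / (1.0 + competitor_conc / k_d_competitor)


def apparent_kd(k_d: float, competitor_conc: float, k_d_competitor: float) -> float:
    """Inverse of :func:`competition_kd`."""
    if k_d <= 0 or k_d_competitor <= 0 or competitor_conc < 0:
        raise ValueError("concentrations and constants must be positive")
    return k_d * (1.0 + competitor_conc / k_d_competitor)


def fold_change(intensity_test: float, intensity_reference: float,
                sd_test: float = 0.0, sd_reference: float = 0.0
                ) -> tuple[float, float]:
    """Intensity ratio with first-order propagated standard deviation."""
    if intensity_reference <= 0:
        raise ValueError("reference intensity must be positive")
    ratio = intensity_test / intensity_reference
    rel = np.sqrt((sd_test / intensity_test) ** 2 +
                  (sd_reference / intensity_reference) ** 2) \
        if intensity_test > 0 else 0.0
    return float(ratio), float(ratio * rel)


def read_titration_csv(path: str, protein_conc: float | None = None
                       ) -> TitrationSeries:
    """Read a titration CSV with columns concentration, intensity and
    optionally replicate; a 'unit' column or '# unit: uM' header line
    declares concentration units (default molar)."""
    unit = "m"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "unit" in first.lower():
        unit = first.split(":")[-1].strip().lower()
        df = pd.read_csv(path, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
        if "unit" in df.columns:
            unit = str(df["unit"].iloc[0]).strip().lower()
    factor = _UNIT_FACTORS.get(unit)
    if factor is None:
        raise ValueError(f"unknown concentration unit {unit!r}")
    df = df.sort_values(["replicate", "concentration"]) \
        if "replicate" in df.columns else df.sort_values("concentration")
    return TitrationSeries(
        concentrations=df["concentration"].to_numpy(dtype=float) * factor,
        intensities=df["intensity"].to_numpy(dtype=float),
        replicates=df["replicate"].to_numpy() if "replicate" in df.columns else None,
        protein_conc=protein_conc,
    )
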