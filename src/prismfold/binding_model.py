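"""Fast-exchange binding thermodynamics: chemical-shift-perturbation
titration fitting, free-energy comparison of dissociation constants, and
population estimation from peak intensities (anomer ratios, STD spectra).

Under fast exchange the observed shift of a resonance is the population-
weighted average of its free and bound values,

    delta_obs(L_tot) = delta_free + (delta_bound - delta_free) * f_bound,

with f_bound the exact 1:1 per-site bound fraction from the quadratic
binding equation.  The three binding sites of the trimer are modeled as
independent and identical, so P_tot is the *site* concentration (three
times the trimer concentration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GAS_CONSTANT_KCAL",
    "TitrationSeries",
    "BindingFit",
    "fraction_bound",
    "fit_kd",
    "delta_delta_g",
    "population_from_intensities",
    "std_difference",
]

GAS_CONSTANT_KCAL = 1.987e-3  # kcal mol^-1 K^-1


@dataclass(frozen=True)
class TitrationSeries:
    """(total ligand concentration, observed shift) points for one resonance."""

    resonance_id: str
    points: tuple  # of (L_tot [M], delta_obs [ppm])
    p_tot: float  # protein *site* concentration, M

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(tuple(p) for p in self.points))
        L = [p[0] for p in self.points]
        if any(x < 0 for x in L):
            raise ValueError("ligand concentrations must be non-negative")
        if any(b <= a for a, b in zip(L, L[1:])):
            raise ValueError("ligand concentrations must be strictly increasing")
        if self.p_tot < 0:
            raise ValueError("protein concentration must be non-negative")

    @property
    def l_tot(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def delta_obs(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass(frozen=True)
class BindingFit:
    resonance_id: str
    k_d: float          # M
    delta_free: float   # ppm
    delta_bound: float  # ppm
    rss: float
    se_kd: float

    def __post_init__(self):
        if self.k_d <= 0:
            raise ValueError("K_D must be positive")


# P_tot/K_D below this: the excess-ligand limit and the exact quadratic
# solution agree to well under 1%, and the limit is used when P_tot == 0.
_EXCESS_LIGAND_RATIO = 1e-3


def fraction_bound(l_tot, p_tot: float, k_d: float):
    """Bound fraction of protein sites for 1:1 per-site binding.

    Exact smaller root of  C^2 - C (L + P + K_D) + L P = 0, divided by P;
    reduces to L / (L + K_D) as P -> 0.  Accepts scalar or array L_tot.
    """
    l_tot = np.asarray(l_tot, dtype=float)
    if np.any(l_tot < 0) or p_tot < 0:
        raise ValueError("concentrations must be non-negative")
    if k_d <= 0:
        raise ValueError("K_D must be positive")
    if p_tot == 0 or p_tot / k_d < _EXCESS_LIGAND_RATIO:
        f = l_tot / (l_tot + k_d)
    else:
        b = l_tot + p_tot + k_d
        disc = np.sqrt(b * b - 4.0 * l_tot * p_tot)
        # numerically stable smaller root
        complex_conc = 2.0 * l_tot * p_tot / (b + disc)
        f = complex_conc / p_tot
    if np.ndim(f) == 0:
        return float(f)
    return f


def _model(params, L, p_tot):
    k_d, d_free, d_bound = params
    return d_free + (d_bound - d_free) * fraction_bound(L, p_tot, k_d)


def fit_kd(series: TitrationSeries, noise_floor: float = 1e-4) -> BindingFit:
    """Least-squares fit of the fast-exchange titration model.

    Multi-start over a K_D grid spanning the sampled ligand range guards
    against local minima; the K_D standard error comes from the Jacobian at
    the optimum.  A series whose total shift change is below ``noise_floor``
    (ppm) is unidentifiable and raises ``ValueError``.
    """
    L = series.l_tot
    y = series.delta_obs
    if len(L) < 4:
        raise ValueError("need at least 4 titration points to fit")
    span = float(np.max(y) - np.min(y))
    if span < noise_floor:
        raise ValueError(
            f"titration series {series.resonance_id!r} is unidentifiable: "
            f"shift range {span:.2e} ppm is below the noise floor"
        )

    l_max = float(np.max(L[L > 0])) if np.any(L > 0) else 1.0
    l_min_pos = float(np.min(L[L > 0])) if np.any(L > 0) else l_max / 100.0
    kd_grid = np.geomspace(l_min_pos / 10.0, l_max * 10.0, 7)

    def residuals(params):
        log_kd, d_free, d_bound = params
        return _model((np.exp(log_kd), d_free, d_bound), L, series.p_tot) - y

    best = None
    d_free0 = float(y[0])
    for kd0 in kd_grid:
        f0 = fraction_bound(L, series.p_tot, kd0)
        fmax = float(np.max(f0))
        d_bound0 = d_free0 + (float(y[-1]) - d_free0) / max(fmax, 1e-6)
        res = least_squares(
            residuals, x0=[np.log(kd0), d_free0, d_bound0], method="lm",
            max_nfev=2000,
        )
        if best is None or res.cost < best.cost:
            best = res
    rss = float(2.0 * best.cost)
    k_d = float(np.exp(best.x[0]))

    # standard error of K_D via the Jacobian in log-space, delta method
    n, p = len(L), 3
    dof = max(n - p, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se_log_kd = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_kd = k_d * se_log_kd
    except np.linalg.LinAlgError:
        se_kd = float("nan")
    return BindingFit(
        resonance_id=series.resonance_id,
        k_d=k_d,
        delta_free=float(best.x[1]),
        delta_bound=float(best.x[2]),
        rss=rss,
        se_kd=se_kd,
    )


def delta_delta_g(k1: float, k2: float, temperature: float = 298.15) -> float:
    """Free-energy difference R T ln(K1/K2) in kcal/mol for two dissociation
    constants (positive when K1 is the weaker affinity)."""
    if k1 <= 0 or k2 <= 0 or temperature <= 0:
        raise ValueError("dissociation constants and temperature must be positive")
    return GAS_CONSTANT_KCAL * temperature * float(np.log(k1 / k2))


def population_from_intensities(intensities, proton_counts=None):
    """Fractional populations from peak intensities (optionally normalized
    by the number of protons contributing to each peak).  Fractions sum to 1."""
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("no intensities given")
    if np.any(x < 0):
        raise ValueError("intensities must be non-negative")
    if proton_counts is not None:
        pc = np.asarray(proton_counts, dtype=float)
        if pc.shape != x.shape or np.any(pc <= 0):
            raise ValueError("proton_counts must match intensities and be positive")
        x = x / pc
    total = float(np.sum(x))
    if total == 0:
        raise ValueError("all intensities are zero")
    return x / total


def std_difference(on_resonance, off_resonance, peak_height_frac: float = 0.05):
    """Saturation-transfer difference: (off - on) spectrum, flagged positive
    peaks, and the bound-state populations of the flagged species.

    ``peak_height_frac`` sets the peak-detection threshold as a fraction of
    the maximal difference amplitude.  Returns (difference, peak_indices,
    populations); with a zero difference the peak list and populations are
    empty.
    """
    on = np.asarray(on_resonance, dtype=float)
    off = np.asarray(off_resonance, dtype=float)
    if on.shape != off.shape:
        raise ValueError(
            f"spectra have mismatched axes: {on.shape} vs {off.shape}"
        )
    diff = off - on
    amp = float(np.max(np.abs(diff))) if diff.size else 0.0
    if amp == 0.0:
        return diff, np.array([], dtype=int), np.array([])
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(diff, height=peak_height_frac * amp)
    if peaks.size == 0:
        return diff, peaks, np.array([])
    pops = population_from_intensities(diff[peaks])
    return diff, peaks, pops
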