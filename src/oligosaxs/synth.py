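"""Synthetic scattering data with known ground truth.

Closed-form scatterers (uniform sphere, prolate ellipsoid, Gaussian
chain), exact Debye sums over bead coordinates, convex mixtures, SEC
elution frame series with buffer background and counting-like noise,
and ideal helix coordinate fixtures.  Every generator is deterministic
under a fixed seed and records the truth needed to score downstream
recovery.

The noise model is Gaussian with σ ∝ √I — photon counting after
radial averaging — with a small floor so uncertainties stay positive
at intensity minima.  "Noiseless" curves carry a nominal 1% σ scale
(intensities exact) so χ²-weighted fits remain meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .curves import ScatteringCurve, SecSeries

__all__ = [
    "default_s_grid",
    "sphere_curve",
    "ellipsoid_curve",
    "gaussian_chain_curve",
    "debye_curve_from_coords",
    "mixture_curve",
    "simulate_sec_series",
    "ideal_helix_coords",
    "SecTruth",
]

#: s-grid matching a typical BM29-style measurement window
S_MIN, S_MAX, N_S = 0.0032, 0.4944, 400

MAX_DEBYE_POINTS = 5000
NOMINAL_REL_SIGMA = 0.01


def default_s_grid(n: int = N_S) -> np.ndarray:
    """Uniform s-grid over 0.0032–0.4944 Å⁻¹."""
    return np.linspace(S_MIN, S_MAX, n)


def _sigma_model(i: np.ndarray, i0: float, noise: float) -> np.ndarray:
    rel = noise if noise > 0 else NOMINAL_REL_SIGMA
    return rel * np.sqrt(np.clip(i, 0.0, None) * i0) + rel * i0 * 1e-3


def _finish(
    s: np.ndarray,
    i: np.ndarray,
    i0: float,
    noise: float,
    seed: int | None,
    label: str,
    concentration: float | None = None,
) -> ScatteringCurve:
    sigma = _sigma_model(i, i0, noise)
    if noise > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, sigma)
    return ScatteringCurve(
        s=s, intensity=i, sigma=sigma, label=label, concentration=concentration
    )


def _sphere_ff(x: np.ndarray) -> np.ndarray:
    """Normalized uniform-sphere amplitude 3(sin x − x cos x)/x³."""
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-6
    xn = x[nz]
    out[nz] = 3.0 * (np.sin(xn) - xn * np.cos(xn)) / xn**3
    small = ~nz
    out[small] = 1.0 - x[small] ** 2 / 10.0
    return out


def sphere_curve(
    radius: float,
    i0: float = 1.0,
    s_grid: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int | None = None,
    concentration: float | None = None,
) -> ScatteringCurve:
    """Uniform sphere: I(s) = I0·[3(sin x − x cos x)/x³]², x = s·R.

    True Rg = √(3/5)·R, Dmax = 2R, volume = 4πR³/3.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    s = default_s_grid() if s_grid is None else np.asarray(s_grid, dtype=float)
    i = i0 * _sphere_ff(s * radius) ** 2
    return _finish(
        s, i, i0, noise, seed, f"sphere R={radius:g}", concentration
    )


def ellipsoid_curve(
    semi_a: float,
    semi_c: float,
    i0: float = 1.0,
    s_grid: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int | None = None,
    n_quad: int = 128,
    concentration: float | None = None,
) -> ScatteringCurve:
    """Orientationally averaged ellipsoid of revolution (a, a, c).

    I(s) = I0 ∫₀¹ Φ²(s·r(u)) du with r(u) = √(a²(1−u²) + c²u²).
    True Rg = √((2a² + c²)/5), Dmax = 2·max(a, c), V = 4πa²c/3.
    """
    if semi_a <= 0 or semi_c <= 0:
        raise ValueError("semi-axes must be positive")
    s = default_s_grid() if s_grid is None else np.asarray(s_grid, dtype=float)
    u, w = np.polynomial.legendre.leggauss(n_quad)
    u = 0.5 * (u + 1.0)  # map to [0, 1]
    w = 0.5 * w
    r_eff = np.sqrt(semi_a**2 * (1 - u**2) + semi_c**2 * u**2)
    x = np.outer(s, r_eff)
    i = i0 * (_sphere_ff(x) ** 2 @ w)
    return _finish(
        s, i, i0, noise, seed,
        f"ellipsoid a={semi_a:g} c={semi_c:g}", concentration,
    )


def gaussian_chain_curve(
    rg: float,
    i0: float = 1.0,
    s_grid: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int | None = None,
    concentration: float | None = None,
) -> ScatteringCurve:
    """Gaussian (Debye) chain: I(s) = I0·2(e^{−u} − 1 + u)/u², u = (sRg)².

    The dimensionless Kratky transform of this curve rises to a
    plateau of 2 at large sRg — the flexible-chain signature.
    """
    if rg <= 0:
        raise ValueError("rg must be positive")
    s = default_s_grid() if s_grid is None else np.asarray(s_grid, dtype=float)
    u = (s * rg) ** 2
    i = np.empty_like(u)
    small = u < 1e-8
    i[small] = 1.0 - u[small] / 3.0
    un = u[~small]
    i[~small] = 2.0 * (np.expm1(-un) + un) / un**2
    i = i0 * i
    return _finish(s, i, i0, noise, seed, f"chain Rg={rg:g}", concentration)


def debye_curve_from_coords(
    coords: np.ndarray,
    s_grid: np.ndarray | None = None,
    form: float | np.ndarray = 1.0,
    noise: float = 0.0,
    seed: int | None = None,
) -> ScatteringCurve:
    """Exact Debye double sum I(s) = ΣᵢΣⱼ fᵢfⱼ sin(s·dᵢⱼ)/(s·dᵢⱼ).

    Direct pairwise evaluation; limited to 5000 points (subsample
    larger coordinate sets first).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) < 1:
        raise ValueError("coords must be an (n, 3) array with n >= 1")
    n = len(coords)
    if n > MAX_DEBYE_POINTS:
        raise ValueError(
            f"{n} points exceed the {MAX_DEBYE_POINTS}-point limit; "
            "subsample the coordinates"
        )
    s = default_s_grid() if s_grid is None else np.asarray(s_grid, dtype=float)
    f = np.broadcast_to(np.asarray(form, dtype=float), (n,))
    self_term = float(np.sum(f**2))
    if n == 1:
        i = np.full_like(s, self_term)
    else:
        d = pdist(coords)
        iu, ju = np.triu_indices(n, k=1)
        wpair = f[iu] * f[ju]
        i = np.empty_like(s)
        for k, sk in enumerate(s):
            if sk == 0:
                i[k] = self_term + 2.0 * wpair.sum()
                continue
            x = sk * d
            i[k] = self_term + 2.0 * float(np.dot(wpair, np.sin(x) / x))
    i0 = self_term if n == 1 else self_term + 2.0 * float(wpair.sum())
    return _finish(s, i, i0, noise, seed, f"debye n={n}")


def mixture_curve(
    components: list[tuple[ScatteringCurve, float]],
) -> ScatteringCurve:
    """Convex combination of curves on a shared grid.

    Intensities combine linearly, σ in weighted quadrature; weights
    must be non-negative and sum to 1.
    """
    if not components:
        raise ValueError("mixture needs at least one component")
    curves, weights = zip(*components)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("weights must be non-negative and sum to 1")
    ref = curves[0]
    for c in curves[1:]:
        if not ref.same_grid(c):
            raise ValueError("mixture components are on different s-grids")
    i = sum(wk * c.intensity for wk, c in zip(w, curves))
    sig = np.sqrt(sum((wk * c.sigma) ** 2 for wk, c in zip(w, curves)))
    return ScatteringCurve(
        s=ref.s, intensity=i, sigma=sig, label="mixture"
    )


@dataclass(frozen=True)
class SecTruth:
    """Ground truth emitted with a simulated SEC-SAXS series."""

    conc: np.ndarray  # mg/ml per frame
    protein: ScatteringCurve  # protein contribution at peak concentration
    buffer_level: float
    contributions: np.ndarray  # (n_frames, n_s) noiseless protein part
    peak_frame: int


def simulate_sec_series(
    protein: ScatteringCurve,
    elution: tuple[float, float, float],
    buffer_level: float = 0.05,
    n_frames: int = 200,
    noise: float = 0.01,
    seed: int = 0,
    composition=None,
) -> tuple[SecSeries, SecTruth]:
    """Simulate a SEC-SAXS frame series with Gaussian elution.

    ``elution = (center_frame, width_frames, peak_conc_mg_ml)``.  Frame
    f carries ``buffer_level + c(f)·protein/c_peak`` plus Gaussian
    noise with σ ∝ √I.  ``composition``, if given, maps a frame
    concentration (mg/ml) to the protein-contribution intensity array
    at that concentration — used to emulate concentration-dependent
    oligomer growth across the peak.
    """
    if n_frames < 20:
        raise ValueError("n_frames must be >= 20")
    center, width, c_peak = elution
    if c_peak < 0 or width <= 0:
        raise ValueError("elution width must be positive, peak conc >= 0")
    s = protein.s
    frames_idx = np.arange(n_frames)
    conc = c_peak * np.exp(-((frames_idx - center) ** 2) / (2.0 * width**2))
    rng = np.random.default_rng(seed)
    scale_ref = float(protein.intensity.max() + buffer_level)
    frames = []
    contributions = np.zeros((n_frames, len(s)))
    for f in range(n_frames):
        if composition is not None and conc[f] > 0:
            contrib = np.asarray(composition(conc[f]), dtype=float)
        elif c_peak > 0:
            contrib = conc[f] * protein.intensity / c_peak
        else:
            contrib = np.zeros_like(s)
        contributions[f] = contrib
        clean = buffer_level + contrib
        sigma = noise * np.sqrt(np.clip(clean, 0, None) * scale_ref)
        sigma = sigma + noise * scale_ref * 1e-3
        noisy = clean + rng.normal(0.0, sigma) if noise > 0 else clean
        frames.append(
            ScatteringCurve(
                s=s,
                intensity=noisy,
                sigma=sigma,
                concentration=float(conc[f]),
                label=f"frame {f}",
            )
        )
    truth = SecTruth(
        conc=conc,
        protein=protein,
        buffer_level=buffer_level,
        contributions=contributions,
        peak_frame=int(round(center)),
    )
    return SecSeries(frames=tuple(frames)), truth


def ideal_helix_coords(
    n_res: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
) -> np.ndarray:
    """Cα trace of an ideal α-helix with its axis along +z.

    ``rise`` is the per-residue translation (Å), ``twist`` the
    per-residue rotation (degrees), ``radius`` the Cα helix radius.
    """
    if n_res < 4:
        raise ValueError("n_res must be >= 4")
    k = np.arange(n_res)
    theta = np.deg2rad(twist) * k
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * k]
    )
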