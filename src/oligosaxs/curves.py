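"""Scattering-curve and SEC-SAXS series containers and text I/O.

The 1D scattering profile I(s) is stored against momentum transfer
``s = 4π sin(θ)/λ`` (scattering angle 2θ) in Å⁻¹, together with
pointwise uncertainties.  SEC-SAXS data are an ordered stack of such
profiles on one shared s-grid, one frame per exposure.

Files are plain 3-column text (s, I, σ) as deposited in SASBDB;
whitespace- and comma-separated dialects are both accepted and
non-numeric header/footer lines are tolerated and preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ScatteringCurve",
    "SecSeries",
    "CurveFormatError",
    "CurveValidationError",
    "read_curve",
    "write_curve",
    "read_series",
]

#: absolute tolerance (Å⁻¹) for deciding that two s-grids are identical
S_GRID_ATOL = 1e-8

MIN_CURVE_POINTS = 8


class CurveValidationError(ValueError):
    """A curve or series violates a structural invariant."""


class CurveFormatError(ValueError):
    """A scattering-curve file could not be parsed."""


def _readonly(a) -> np.ndarray:
    out = np.array(a, dtype=float)
    out.setflags(write=False)
    return out


@dataclass(frozen=True)
class ScatteringCurve:
    """One 1D scattering profile I(s) with uncertainties.

    Immutable after validation; every transform returns a new curve so
    provenance is never destroyed in place.

    Parameters
    ----------
    s : array
        Momentum transfer, Å⁻¹, non-negative and strictly increasing.
    intensity : array
        Scattered intensity, arbitrary units.
    sigma : array
        Pointwise uncertainty of ``intensity``; must be positive
        wherever the intensity is finite.
    wavelength : float, optional
        X-ray wavelength in Å (metadata only).
    concentration : float, optional
        Sample concentration in mg/ml (metadata only).
    label : str
        Free-text identifier.
    header : str
        Header text preserved from the source file, if any.
    """

    s: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    wavelength: float | None = None
    concentration: float | None = None
    label: str = ""
    header: str = ""

    def __post_init__(self) -> None:
        s = _readonly(self.s)
        intensity = _readonly(self.intensity)
        sigma = _readonly(self.sigma)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "sigma", sigma)
        n = len(s)
        if not (len(intensity) == len(sigma) == n):
            raise CurveValidationError(
                f"s, intensity, sigma must have equal length; got "
                f"{n}, {len(intensity)}, {len(sigma)}"
            )
        if n < MIN_CURVE_POINTS:
            raise CurveValidationError(
                f"curve needs at least {MIN_CURVE_POINTS} points, got {n}"
            )
        if np.any(s < 0):
            raise CurveValidationError("s values must be non-negative")
        if np.any(np.diff(s) <= 0):
            i = int(np.argmax(np.diff(s) <= 0))
            raise CurveValidationError(
                f"s must be strictly increasing (violated after index {i})"
            )
        finite = np.isfinite(intensity)
        if np.any(~(sigma[finite] > 0)):
            raise CurveValidationError(
                "sigma must be > 0 wherever intensity is finite"
            )

    def __len__(self) -> int:
        return len(self.s)

    @property
    def s_min(self) -> float:
        return float(self.s[0])

    @property
    def s_max(self) -> float:
        return float(self.s[-1])

    def with_(self, **changes) -> "ScatteringCurve":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def same_grid(self, other: "ScatteringCurve", atol: float = S_GRID_ATOL) -> bool:
        return len(self) == len(other) and bool(
            np.allclose(self.s, other.s, atol=atol, rtol=0.0)
        )


@dataclass(frozen=True)
class SecSeries:
    """Ordered SEC-SAXS frame stack on one shared s-grid.

    ``frame_index`` runs 0..n-1 without gaps; ``exposure`` is the
    per-frame exposure time in seconds; ``uv280`` is an optional
    per-frame UV absorbance trace (used for concentration estimates).
    """

    frames: tuple[ScatteringCurve, ...]
    exposure: float = 1.0
    uv280: np.ndarray | None = None

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        object.__setattr__(self, "frames", frames)
        if len(frames) < 2:
            raise CurveValidationError("a SEC series needs at least 2 frames")
        ref = frames[0]
        for i, fr in enumerate(frames[1:], start=1):
            if not ref.same_grid(fr):
                raise CurveValidationError(
                    f"frame {i} is not on the shared s-grid of frame 0"
                )
        if self.uv280 is not None:
            uv = _readonly(self.uv280)
            if len(uv) != len(frames):
                raise CurveValidationError(
                    "uv280 trace length must equal the frame count"
                )
            object.__setattr__(self, "uv280", uv)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> ScatteringCurve:
        return self.frames[i]

    @property
    def frame_index(self) -> np.ndarray:
        return np.arange(len(self.frames))

    @property
    def s(self) -> np.ndarray:
        return self.frames[0].s

    def intensity_matrix(self) -> np.ndarray:
        """(n_frames, n_s) intensity array."""
        return np.stack([f.intensity for f in self.frames])

    def sigma_matrix(self) -> np.ndarray:
        return np.stack([f.sigma for f in self.frames])


# ----------------------------------------------------------------------
# text I/O


def _parse_row(line: str, dialect: str) -> tuple[float, float, float] | None:
    txt = line.strip()
    if not txt:
        return None
    if dialect in ("auto", "comma") and "," in txt:
        parts = [p for p in txt.replace(",", " ").split() if p]
    else:
        parts = txt.split()
    if len(parts) < 3:
        return None
    try:
        return float(parts[0]), float(parts[1]), float(parts[2])
    except ValueError:
        return None


def read_curve(
    path: str | Path,
    dialect: str = "auto",
    s_unit: str = "1/A",
    label: str | None = None,
) -> ScatteringCurve:
    """Read a 3-column (s, I, σ) text file into a :class:`ScatteringCurve`.

    Lines that do not parse as three floats are treated as header or
    footer text and preserved in ``curve.header``.  ``s_unit`` may be
    ``"1/A"`` (default) or ``"1/nm"``; nm⁻¹ input is converted to Å⁻¹
    explicitly — there is no unit guessing.
    """
    if s_unit not in ("1/A", "1/nm"):
        raise ValueError(f"unknown s unit {s_unit!r}; use '1/A' or '1/nm'")
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    header_lines: list[str] = []
    first_bad: tuple[int, str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            row = _parse_row(line, dialect)
            if row is None:
                if line.strip():
                    header_lines.append(line.rstrip("\n"))
                    if first_bad is None:
                        first_bad = (lineno, line.strip())
            else:
                rows.append(row)
    if len(rows) < MIN_CURVE_POINTS:
        where = (
            f"; first non-parsing line {first_bad[0]}: {first_bad[1]!r}"
            if first_bad
            else ""
        )
        raise CurveFormatError(
            f"{path}: found only {len(rows)} parseable (s, I, sigma) rows"
            f"{where}"
        )
    data = np.array(rows)
    s, intensity, sigma = data[:, 0], data[:, 1], data[:, 2]
    if s_unit == "1/nm":
        s = s * 0.1
    header = "\n".join(header_lines)
    wavelength, concentration = _meta_from_header(header)
    try:
        return ScatteringCurve(
            s=s,
            intensity=intensity,
            sigma=sigma,
            wavelength=wavelength,
            concentration=concentration,
            label=label if label is not None else path.stem,
            header=header,
        )
    except CurveValidationError as exc:
        raise CurveValidationError(f"{path}: {exc}") from exc


_META_KEYS = {"wavelength": "wavelength", "concentration": "concentration"}


def _meta_from_header(header: str) -> tuple[float | None, float | None]:
    out: dict[str, float] = {}
    for token in header.replace("|", " ").split():
        if "=" in token:
            key, _, val = token.partition("=")
            key = key.strip().lower()
            if key in _META_KEYS:
                try:
                    out[key] = float(val)
                except ValueError:
                    pass
    return out.get("wavelength"), out.get("concentration")


def write_curve(curve: ScatteringCurve, path: str | Path) -> Path:
    """Write a curve as 3-column text, one metadata header line first.

    ``read_curve(write_curve(c))`` reproduces (s, I, σ) to the printed
    precision (13 significant digits).
    """
    path = Path(path)
    meta = [f"# {curve.label}" if curve.label else "# scattering curve"]
    if curve.wavelength is not None:
        meta.append(f"wavelength={curve.wavelength:g}")
    if curve.concentration is not None:
        meta.append(f"concentration={curve.concentration:g}")
    lines = [" | ".join(meta)]
    lines.append("#         s              I(s)           sigma")
    for s, i, sig in zip(curve.s, curve.intensity, curve.sigma):
        lines.append(f"{s:.12e} {i:.12e} {sig:.12e}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_series(
    paths: Sequence[str | Path] | Iterable[str | Path],
    dialect: str = "auto",
    s_unit: str = "1/A",
    exposure: float = 1.0,
) -> SecSeries:
    """Read an ordered list of frame files into a :class:`SecSeries`."""
    paths = list(paths)
    if len(paths) < 2:
        raise CurveValidationError("need at least 2 frame files")
    frames = [read_curve(p, dialect=dialect, s_unit=s_unit) for p in paths]
    ref = frames[0]
    for i, fr in enumerate(frames[1:], start=1):
        if not ref.same_grid(fr):
            raise CurveValidationError(
                f"frame {i} ({paths[i]}) is not on the s-grid of frame 0"
            )
    return SecSeries(frames=tuple(frames), exposure=exposure)
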