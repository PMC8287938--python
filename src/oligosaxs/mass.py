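"""Molecular-weight estimation and oligomeric-state assignment.

Two MW routes are implemented:

* the forward-scattering ratio against a standard of known mass,
  MWᵘ = MWˢ · [I(0)ᵘ/cᵘ] / [I(0)ˢ/cˢ], valid for ideal dilute
  particles where I(0) ∝ c·MW;
* the Porod-volume rule of thumb MW(Da) = Vp(Å³)/1.66.

An oligomeric state is then the integer number of monomer units
consistent with the estimate and its uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .curves import CurveValidationError, ScatteringCurve, SecSeries
from .guinier import GuinierError, auto_guinier
from .reduction import subtract_buffer

__all__ = [
    "MassStandard",
    "MassEstimate",
    "OligomerAssignment",
    "mw_from_i0_standard",
    "mw_from_porod",
    "assign_oligomer",
    "per_frame_mw",
    "POROD_DIVISOR",
]

#: Da per Å³ of Porod volume for an average-density protein
POROD_DIVISOR = 1.66


@dataclass(frozen=True)
class MassStandard:
    """A reference measurement of known molecular weight.

    ``i0_s`` is the standard's forward scattering, ``conc_s`` its
    concentration in mg/ml, ``mw_s`` its molecular weight in kDa.
    """

    i0_s: float
    conc_s: float
    mw_s: float
    label: str = "standard"

    def __post_init__(self) -> None:
        if min(self.i0_s, self.conc_s, self.mw_s) <= 0:
            raise CurveValidationError(
                "standard I(0), concentration and MW must all be positive"
            )


@dataclass(frozen=True)
class MassEstimate:
    """A molecular-weight estimate in kDa with method provenance."""

    mw: float
    method: str  # "i0_standard" | "porod"
    inputs_used: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise CurveValidationError("estimated MW must be positive")
        if self.method not in ("i0_standard", "porod"):
            raise CurveValidationError(f"unknown MW method {self.method!r}")


@dataclass(frozen=True)
class OligomerAssignment:
    """Inferred n-mer count (best and range) for a monomer unit mass."""

    n_best: int
    n_range: tuple[int, int]
    monomer_unit_mw: float
    relative_error: float

    def __post_init__(self) -> None:
        lo, hi = self.n_range
        if not (lo <= self.n_best <= hi):
            raise CurveValidationError("n_best must lie inside n_range")


def mw_from_i0_standard(
    i0_u: float, conc_u: float, std: MassStandard
) -> MassEstimate:
    """MW of an unknown from its I(0)/concentration ratio vs a standard."""
    if i0_u <= 0 or conc_u <= 0:
        raise CurveValidationError("I(0) and concentration must be positive")
    mw = std.mw_s * (i0_u / conc_u) / (std.i0_s / std.conc_s)
    return MassEstimate(
        mw=mw,
        method="i0_standard",
        inputs_used={
            "i0_u": i0_u,
            "conc_u": conc_u,
            "i0_s": std.i0_s,
            "conc_s": std.conc_s,
            "mw_s": std.mw_s,
        },
    )


def mw_from_porod(vp: float) -> MassEstimate:
    """MW (kDa) from the Porod volume in Å³: MW(Da) = Vp/1.66."""
    if vp <= 0:
        raise CurveValidationError("Porod volume must be positive")
    return MassEstimate(
        mw=vp / POROD_DIVISOR / 1000.0,
        method="porod",
        inputs_used={"vp": vp, "divisor": POROD_DIVISOR},
    )


def assign_oligomer(
    est: MassEstimate,
    monomer_unit_mw: float,
    delta: float | None = None,
) -> OligomerAssignment:
    """Assign the n-mer count consistent with a mass estimate.

    ``delta`` is the absolute MW uncertainty in kDa (default: 10% of
    the estimate); the range is [floor((mw−δ)/unit), ceil((mw+δ)/unit)]
    clipped to ≥ 1.
    """
    if monomer_unit_mw <= 0:
        raise CurveValidationError("monomer unit mass must be positive")
    mw = est.mw
    if delta is None:
        delta = 0.10 * mw
    if delta >= mw:
        raise CurveValidationError("uncertainty must be smaller than the MW")
    n_best = max(1, round(mw / monomer_unit_mw))
    lo = max(1, math.floor((mw - delta) / monomer_unit_mw))
    hi = max(lo, math.ceil((mw + delta) / monomer_unit_mw))
    n_best = min(max(n_best, lo), hi)
    return OligomerAssignment(
        n_best=n_best,
        n_range=(lo, hi),
        monomer_unit_mw=monomer_unit_mw,
        relative_error=abs(mw - n_best * monomer_unit_mw) / mw,
    )


def per_frame_mw(
    series: SecSeries,
    buffer: ScatteringCurve,
    std: MassStandard,
    conc_trace: np.ndarray,
    srg_limit: float = 1.3,
) -> list[MassEstimate | None]:
    """Frame-by-frame MW across a SEC-SAXS chromatogram.

    Each frame with positive concentration is buffer-subtracted and
    Guinier-fitted; its I(0) and concentration give the MW against the
    standard.  Frames with no usable Guinier region (buffer-only
    frames, tails) are reported as None — never fabricated.  The
    result is invariant under a joint rescaling of all intensities and
    the standard's I(0).
    """
    conc = np.asarray(conc_trace, dtype=float)
    if len(conc) != len(series):
        raise CurveValidationError("conc_trace length must match the series")
    out: list[MassEstimate | None] = []
    for f, frame in enumerate(series.frames):
        c = conc[f]
        if not (np.isfinite(c) and c > 0):
            out.append(None)
            continue
        sub = subtract_buffer(frame, buffer)
        try:
            g = auto_guinier(sub, srg_limit=srg_limit)
            est = mw_from_i0_standard(g.i0, c, std)
        except (GuinierError, CurveValidationError):
            out.append(None)
            continue
        est = MassEstimate(
            mw=est.mw,
            method=est.method,
            inputs_used={**est.inputs_used, "frame": f, "rg": g.rg},
        )
        out.append(est)
    if all(e is None for e in out):
        raise GuinierError("no frame yielded a usable MW estimate")
    return out
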