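"""End-to-end analysis pipeline with a machine-readable run report.

``run_process`` chains reduction → Guinier → dimensionless Kratky →
Dmax/P(r) → Porod → molecular weight (both routes) → oligomer
assignment.  A stage that fails is recorded with its reason and its
dependents are skipped — downstream numbers are never fabricated.
The report carries the fully resolved parameter set, so re-running
with it reproduces the report exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np

from .curves import ScatteringCurve, SecSeries
from .defaults import DEFAULTS
from .guinier import (
    auto_guinier,
    dimensionless_kratky,
    globularity_metrics,
)
from .mass import (
    MassStandard,
    assign_oligomer,
    mw_from_i0_standard,
    mw_from_porod,
)
from .realspace import estimate_dmax, ift_pr, porod_volume
from .reduction import reduce_series

__all__ = ["run_process", "report_to_json"]


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_process(
    data: SecSeries | ScatteringCurve,
    standard: MassStandard | None = None,
    concentration: float | None = None,
    monomer_unit_mw: float | None = None,
    config: dict | None = None,
    dmax_search: tuple[float, float] | None = None,
    source_paths: list[str] | None = None,
) -> dict:
    """Run the full solution-scattering analysis and return the report.

    ``data`` is either a SEC-SAXS series (reduced internally) or an
    already background-subtracted curve.  ``standard`` enables the
    I(0)-ratio MW route (requires ``concentration`` of the sample, or
    curve metadata); ``monomer_unit_mw`` (kDa) enables oligomer
    assignment.
    """
    cfg = dict(DEFAULTS)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)

    report: dict[str, Any] = {
        "inputs": {
            "kind": type(data).__name__,
            "paths": [
                {"path": str(p), "sha256": _checksum(p)}
                for p in (source_paths or [])
            ],
        },
        "parameters": _to_plain(cfg),
        "results": {},
        "failures": {},
        "warnings": [],
    }
    results = report["results"]
    failures = report["failures"]

    # --- reduction ----------------------------------------------------
    if isinstance(data, SecSeries):
        try:
            curve, info = reduce_series(
                data,
                n_peak_frames=cfg["n_peak_frames"],
                buffer_margin=cfg["buffer_margin"],
            )
            results["reduction"] = info
        except Exception as exc:
            failures["reduction"] = str(exc)
            return report
    else:
        curve = data

    # --- Guinier ------------------------------------------------------
    try:
        g = auto_guinier(
            curve,
            srg_limit=cfg["srg_limit"],
            min_points=cfg["min_points"],
            r2_min=cfg["r2_min"],
            max_first_skip=cfg["max_first_skip"],
        )
        results["guinier"] = _to_plain(g)
    except Exception as exc:
        failures["guinier"] = str(exc)
        g = None

    # --- Kratky -------------------------------------------------------
    if g is not None:
        try:
            k = dimensionless_kratky(curve, g)
            metrics = globularity_metrics(
                k, flex_threshold=cfg["flex_threshold"]
            )
            results["kratky"] = {
                "peak_x": k.peak_x,
                "peak_y": k.peak_y,
                "high_angle_mean": k.high_angle_mean,
                **_to_plain(metrics),
            }
        except Exception as exc:
            failures["kratky"] = str(exc)

    # --- P(r) / Dmax --------------------------------------------------
    pr = None
    if g is not None:
        try:
            if dmax_search is None:
                dmax_search = (1.2 * g.rg, 5.0 * g.rg)
            dmax, _trace = estimate_dmax(curve, dmax_search)
            pr = ift_pr(
                curve,
                dmax,
                alpha=cfg["alpha"],
                n_bins=cfg["n_bins"],
                nonneg=cfg["nonneg"],
            )
            results["pofr"] = {
                "dmax": pr.dmax,
                "alpha": pr.alpha,
                "chi2": pr.chi2,
                "rg_est": pr.rg_est,
                "i0_est": pr.i0_est,
            }
        except Exception as exc:
            failures["pofr"] = str(exc)

    # --- Porod + MW ---------------------------------------------------
    porod = None
    if g is not None:
        try:
            porod = porod_volume(
                curve,
                g,
                s_cut=cfg["s_cut"],
                subtract_background=cfg["porod_background"],
            )
            results["porod"] = _to_plain(porod)
        except Exception as exc:
            failures["porod"] = str(exc)

    estimates = {}
    if porod is not None:
        est = mw_from_porod(porod.vp)
        estimates["porod"] = est
        results["mw_porod_kda"] = est.mw
    if g is not None and standard is not None:
        conc = (
            concentration
            if concentration is not None
            else curve.concentration
        )
        if conc is None:
            failures["mw_i0"] = (
                "sample concentration unavailable; I(0)-route MW skipped"
            )
        else:
            est = mw_from_i0_standard(g.i0, conc, standard)
            estimates["i0_standard"] = est
            results["mw_i0_kda"] = est.mw
    elif standard is None:
        results["mw_i0_kda"] = None
        report["warnings"].append(
            "no mass standard supplied; I(0)-route MW unavailable"
        )

    # --- oligomer assignment -----------------------------------------
    if monomer_unit_mw is not None and estimates:
        primary = estimates.get("i0_standard") or estimates.get("porod")
        try:
            assignment = assign_oligomer(
                primary,
                monomer_unit_mw,
                delta=cfg["oligomer_delta_frac"] * primary.mw,
            )
            results["oligomer"] = _to_plain(assignment)
        except Exception as exc:
            failures["oligomer"] = str(exc)

    return report


def report_to_json(report: dict, path: str | Path | None = None) -> str:
    """Serialize a run report to JSON (optionally writing it)."""
    text = json.dumps(_to_plain(report), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
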