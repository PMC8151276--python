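"""BRET ratios, fold responses, signal/noise, calls, and saturation fits.

A well's BRET ratio is acceptor emission over donor emission. The fold
response for a (construct, tracer, concentration) is the replicate-averaged
tracer-alone BRET over the replicate-averaged competitor-control BRET;
interactions at or above 1.5-fold are called positive. Signal over noise is
(BRET_tracer - mean control) / sample SD of the control replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from gpcrtracer.errors import SchemaError
from gpcrtracer.synthetic import TRACER_ALONE, TRACER_PLUS_COMPETITOR

FOLD_THRESHOLD = 1.5

RESULT_COLUMNS = [
    "construct", "tracer", "concentration_nM",
    "bret_tracer", "bret_control", "fold_response", "signal_noise", "positive",
]


def bret_ratio(donor_em: float, acceptor_em: float) -> float:
    """Acceptor emission divided by donor emission."""
    if donor_em <= 0:
        raise ValueError(f"donor emission must be positive, got {donor_em}")
    if acceptor_em < 0:
        raise ValueError(f"acceptor emission must be non-negative, got {acceptor_em}")
    return acceptor_em / donor_em


def fold_response(
    bret_tracer: float, bret_control: float, threshold: float = FOLD_THRESHOLD
) -> tuple[float, bool]:
    """Fold response and its positivity call (inclusive threshold)."""
    if bret_control <= 0:
        raise ValueError(f"control BRET must be positive, got {bret_control}")
    ratio = bret_tracer / bret_control
    # inclusive boundary robust to float rounding (0.15/0.10 counts as 1.5)
    positive = ratio >= threshold or math.isclose(ratio, threshold, rel_tol=1e-9)
    return ratio, bool(positive)


def signal_noise(bret_tracer: float, control_replicates) -> float:
    """(BRET_tracer - mean controls) / sample SD of controls; NaN if undefined."""
    controls = np.asarray(list(control_replicates), dtype=float)
    if controls.size < 2:
        raise ValueError("signal/noise needs at least 2 control replicates")
    sd = controls.std(ddof=1)
    # spread below float-rounding scale counts as zero (undefined ratio)
    if sd <= 1e-10 * max(np.abs(controls).max(), np.finfo(float).tiny):
        return float("nan")
    return float((bret_tracer - controls.mean()) / sd)


def _require_plate_schema(plate: pd.DataFrame) -> None:
    needed = {"construct", "tracer", "concentration_nM", "condition",
              "donor_em", "acceptor_em"}
    missing = needed - set(plate.columns)
    if missing:
        raise SchemaError(f"plate table missing columns: {sorted(missing)}")


def with_bret(plate: pd.DataFrame) -> pd.DataFrame:
    """Plate table with a per-well ``bret`` ratio column appended."""
    _require_plate_schema(plate)
    out = plate.copy()
    out["bret"] = [
        bret_ratio(d, a) for d, a in zip(out["donor_em"], out["acceptor_em"])
    ]
    return out


def screen_summary(
    plate: pd.DataFrame,
    tracer: str | None = None,
    concentrations=None,
    threshold: float = FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Per (construct, tracer, concentration) screen statistics.

    Replicate wells are averaged per condition before the ratio. Groups
    missing either condition are skipped with a warning. Signal/noise is NaN
    when fewer than 2 control replicates (or zero spread) are available.
    """
    wells = with_bret(plate)
    if tracer is not None:
        wells = wells[wells["tracer"] == tracer]
    if concentrations is not None:
        wells = wells[wells["concentration_nM"].isin(list(concentrations))]

    rows = []
    for (construct, trc, conc), group in wells.groupby(
        ["construct", "tracer", "concentration_nM"], sort=True
    ):
        alone = group.loc[group["condition"] == TRACER_ALONE, "bret"]
        control = group.loc[group["condition"] == TRACER_PLUS_COMPETITOR, "bret"]
        if alone.empty or control.empty:
            warnings.warn(
                f"skipping {construct}/{trc} at {conc} nM: missing paired condition",
                stacklevel=2,
            )
            continue
        bt, bc = float(alone.mean()), float(control.mean())
        fold, positive = fold_response(bt, bc, threshold=threshold)
        s2n = signal_noise(bt, control) if len(control) >= 2 else float("nan")
        rows.append(
            {
                "construct": construct,
                "tracer": trc,
                "concentration_nM": conc,
                "bret_tracer": bt,
                "bret_control": bc,
                "fold_response": fold,
                "signal_noise": s2n,
                "positive": positive,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def binding_profile(results: pd.DataFrame) -> dict:
    """Constructs positive at each concentration, plus those retained.

    "Retained" means positive at the lowest tested concentration.
    """
    if results.empty:
        return {"positive_at": {}, "retained": []}
    positive_at = {
        float(conc): sorted(
            results.loc[
                (results["concentration_nM"] == conc) & results["positive"],
                "construct",
            ].unique()
        )
        for conc in sorted(results["concentration_nM"].unique())
    }
    lowest = min(positive_at)
    return {"positive_at": positive_at, "retained": positive_at[lowest]}


@dataclass(frozen=True)
class SaturationFit:
    """One-site hyperbola fit of background-corrected BRET."""

    bmax: float
    ec50: float
    residual_sd: float
    corrected: pd.DataFrame  # per-concentration background-corrected BRET
    success: bool


def _hyperbola(c, bmax, ec50):
    return bmax * c / (ec50 + c)


def fit_saturation(
    concentrations, tracer_bret, competitor_bret
) -> SaturationFit:
    """Fit ``bmax*c/(ec50+c)`` to background-corrected BRET by least squares.

    The correction subtracts the paired competitor BRET at each
    concentration. Non-convergence yields ``success=False``, never a raise.
    """
    c = np.asarray(concentrations, dtype=float)
    corrected = np.asarray(tracer_bret, dtype=float) - np.asarray(
        competitor_bret, dtype=float
    )
    if c.size < 4:
        raise ValueError("saturation fit needs >= 4 concentrations")
    table = pd.DataFrame({"concentration_nM": c, "corrected_bret": corrected})
    try:
        p0 = (max(corrected.max(), 1e-6), float(np.median(c)))
        popt, _ = curve_fit(
            _hyperbola, c, corrected, p0=p0,
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return SaturationFit(
            bmax=float("nan"), ec50=float("nan"), residual_sd=float("nan"),
            corrected=table, success=False,
        )
    residuals = corrected - _hyperbola(c, *popt)
    return SaturationFit(
        bmax=float(popt[0]),
        ec50=float(popt[1]),
        residual_sd=float(np.sqrt(np.mean(residuals**2))),
        corrected=table,
        success=True,
    )


def fit_saturation_table(series: pd.DataFrame) -> SaturationFit:
    """Fit a dose-series plate table (replicates averaged per condition)."""
    wells = with_bret(series)
    per = wells.pivot_table(
        index="concentration_nM", columns="condition", values="bret", aggfunc="mean"
    )
    for cond in (TRACER_ALONE, TRACER_PLUS_COMPETITOR):
        if cond not in per.columns:
            raise SchemaError(f"series missing condition {cond!r}")
    per = per.sort_index()
    return fit_saturation(
        per.index.to_numpy(), per[TRACER_ALONE].to_numpy(),
        per[TRACER_PLUS_COMPETITOR].to_numpy(),
    )
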