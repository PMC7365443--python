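"""Functional-assay arithmetic: enzyme kinetics, metabolic flux, respirometry,
sphere-formation efficiency, and the two-tail Student t-test.

Enzyme activities come from the slope of a 340 nm NAD(P)H absorbance trace:
either the earliest linear window (initial-rate assays such as LDH/PK, which
start at maximal velocity) or the steepest linear window (coupled assays such
as HK, which accelerate into a log phase).  Slopes convert to enzyme units
via the NAD(P)H extinction coefficient (6.22 mM⁻¹cm⁻¹ at 340 nm):
1 U = 1 µmol substrate converted per minute at 25 °C.

Respirometry summaries follow the intact-cell protocol: routine respiration
(Cr), the oligomycin-inhibited leak rate (CrO), the FCCP-uncoupled maximal
capacity (CrU, maximum over titration boluses), each corrected by subtracting
residual non-mitochondrial oxygen consumption (ROX).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssayConfig",
    "PhaseFit",
    "detect_linear_phase",
    "activity_from_slope",
    "metabolite_rates",
    "respirometry_summary",
    "sphere_formation_efficiency",
    "students_t_test",
]

#: glycolysis yields at most 2 lactate per glucose; ratios above are flagged
LACTATE_GLUCOSE_MAX = 2.0

#: |slope| below this (absorbance/min) is treated as no measurable rate
MIN_RATE_A_PER_MIN = 1e-4


@dataclass
class AssayConfig:
    """Physical constants and detection settings of one cuvette assay."""

    extinction_coeff: float = 6.22   # mM^-1 cm^-1, NAD(P)H at 340 nm
    path_cm: float = 1.0
    volume_mL: float = 1.0
    protein_mg: float = 1.0
    direction: str = "decrease"      # expected absorbance change
    mode: str = "initial_rate"       # or "max_rate" for accelerating assays
    r2_min: float = 0.98
    window_points: int = 10

    def validate(self) -> None:
        for name in ("extinction_coeff", "path_cm", "volume_mL", "protein_mg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.direction not in ("increase", "decrease"):
            raise ValueError("direction must be 'increase' or 'decrease'")
        if self.mode not in ("initial_rate", "max_rate"):
            raise ValueError("mode must be 'initial_rate' or 'max_rate'")
        if not 0 < self.r2_min <= 1:
            raise ValueError("r2_min must be in (0, 1]")
        if self.window_points < 3:
            raise ValueError("window_points must be >= 3")


@dataclass
class PhaseFit:
    """One sliding-window line: slope in absorbance/min."""

    start: int
    stop: int                 # [start, stop)
    slope: float
    intercept: float
    r2: float
    below_min_rate: bool = False


class NoLinearPhaseError(RuntimeError):
    pass


def _window_fits(t_min: np.ndarray, y: np.ndarray, w: int):
    """(slope, intercept, r2) for every window of width w; vectorised."""
    n = y.size - w + 1
    idx = np.arange(w)[None, :] + np.arange(n)[:, None]
    tw, yw = t_min[idx], y[idx]
    tm, ym = tw.mean(axis=1, keepdims=True), yw.mean(axis=1, keepdims=True)
    sxx = ((tw - tm) ** 2).sum(axis=1)
    sxy = ((tw - tm) * (yw - ym)).sum(axis=1)
    syy = ((yw - ym) ** 2).sum(axis=1)
    slope = sxy / sxx
    intercept = ym[:, 0] - slope * tm[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), 1.0)  # flat window: perfect constant fit
    return slope, intercept, r2


def detect_linear_phase(trace: pd.DataFrame, cfg: AssayConfig) -> PhaseFit:
    """Find the assay's linear phase by sliding-window least squares.

    ``mode='initial_rate'``: earliest window with r² ≥ r2_min whose slope sign
    matches the expected direction; ``mode='max_rate'``: the window maximising
    |slope| subject to r² ≥ r2_min.  A slope smaller than the minimum
    measurable rate is returned but flagged ``below_min_rate`` (direction is
    then not enforced — a flat trace has no meaningful sign).
    """
    cfg.validate()
    t = trace["time_s"].to_numpy(float)
    y = trace.iloc[:, 1].to_numpy(float)
    if t.size < 10:
        raise ValueError("trace must have at least 10 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("trace times must be strictly increasing")
    w = cfg.window_points
    if t.size < w:
        raise ValueError(f"trace shorter than window_points={w}")

    slope, intercept, r2 = _window_fits(t / 60.0, y, w)
    ok = r2 >= cfg.r2_min
    if not ok.any():
        best = int(np.argmax(r2))
        raise NoLinearPhaseError(
            f"no {w}-point window reaches r2 >= {cfg.r2_min}; "
            f"best r2={r2[best]:.4f} at window [{best}, {best + w})"
        )

    want = 1.0 if cfg.direction == "increase" else -1.0
    measurable = np.abs(slope) >= MIN_RATE_A_PER_MIN
    if cfg.mode == "initial_rate":
        cand = ok & ((np.sign(slope) == want) | ~measurable)
        if not cand.any():
            raise NoLinearPhaseError(
                f"no linear window with slope sign matching direction={cfg.direction!r}"
            )
        i = int(np.flatnonzero(cand)[0])
    else:  # max_rate
        masked = np.where(ok, np.abs(slope), -np.inf)
        i = int(np.argmax(masked))

    fit = PhaseFit(
        start=i, stop=i + w,
        slope=float(slope[i]), intercept=float(intercept[i]), r2=float(min(r2[i], 1.0)),
        below_min_rate=bool(abs(slope[i]) < MIN_RATE_A_PER_MIN),
    )
    if fit.below_min_rate:
        logger.warning("detected slope %.3g A/min is below the minimum measurable rate", fit.slope)
    return fit


def activity_from_slope(fit: PhaseFit, cfg: AssayConfig) -> dict:
    """Convert an absorbance slope to enzyme units.

    ``U = (|slope| [A/min] / (ε·l)) · V``: A/min over ε·l gives mM/min, times
    the cuvette volume in mL gives µmol/min.  Specific activity is U per mg
    protein in the cuvette.
    """
    cfg.validate()
    rate_mM_per_min = abs(fit.slope) / (cfg.extinction_coeff * cfg.path_cm)
    units = rate_mM_per_min * cfg.volume_mL
    return {
        "activity_U": units,
        "specific_activity_U_per_mg": units / cfg.protein_mg,
        "extinction_coeff": cfg.extinction_coeff,
        "path_cm": cfg.path_cm,
        "volume_mL": cfg.volume_mL,
        "protein_mg": cfg.protein_mg,
    }


def metabolite_rates(panel: pd.DataFrame | dict) -> dict:
    """Glucose consumption and lactate production rates (µmol·h⁻¹·mg⁻¹).

    Consumption is the medium glucose lost between 0 h and the endpoint,
    production the medium lactate gained, each scaled by volume and normalised
    to incubation time and protein.  The lactate/glucose ratio is capped
    biologically at 2 (glycolytic stoichiometry); values outside (0, 2] are
    flagged with a warning, not an error.
    """
    row = panel.iloc[0] if isinstance(panel, pd.DataFrame) else pd.Series(panel)
    dt, vol, prot = float(row["dt_h"]), float(row["volume_mL"]), float(row["protein_mg"])
    if dt <= 0:
        raise ValueError("dt_h must be > 0")
    if vol <= 0 or prot <= 0:
        raise ValueError("volume_mL and protein_mg must be > 0")

    consumption = (row["glucose_0"] - row["glucose_4"]) * vol / (dt * prot)
    production = (row["lactate_4"] - row["lactate_0"]) * vol / (dt * prot)
    if consumption > 0:
        ratio = production / consumption
        if not 0.0 < ratio <= LACTATE_GLUCOSE_MAX and production != 0:
            warnings.warn(
                f"lactate/glucose ratio {ratio:.2f} outside the glycolytic range (0, 2]: "
                "non-glycolytic lactate sources or assay error",
                stacklevel=2,
            )
    else:
        ratio = np.nan
        warnings.warn("non-positive glucose consumption; lactate/glucose ratio undefined",
                      stacklevel=2)
    out = {
        "glucose_consumption": float(consumption),
        "lactate_production": float(production),
        "lactate_glucose_ratio": float(ratio),
    }
    if "intracellular_lactate_umol" in row:
        out["intracellular_lactate_per_mg"] = float(row["intracellular_lactate_umol"]) / prot
    return out


def _segment_mean(t, y, start, stop, settle_s, plateau_s):
    lo = start + settle_s
    hi = stop
    if hi - lo < plateau_s:
        raise ValueError(
            f"segment [{start}, {stop}) leaves {hi - lo:.0f}s after settle_s={settle_s}, "
            f"need >= plateau_s={plateau_s}"
        )
    sel = (t >= lo) & (t < hi)
    vals = y[sel]
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return mean, sem, int(vals.size)


def respirometry_summary(
    trace: pd.DataFrame,
    events: list[tuple[str, float]],
    *,
    settle_s: float = 30.0,
    plateau_s: float = 30.0,
    rox_constant: float | None = None,
) -> dict:
    """Summarise an intact-cell oxygen-consumption trace.

    Cr = mean of the pre-oligomycin steady segment; CrO = post-oligomycin
    plateau; CrU = max over per-FCCP-bolus plateau means; ROX = post-inhibitor
    plateau if an inhibitor event exists, else ``rox_constant`` (default 0,
    with a warning).  Corrected values subtract ROX; spare capacity =
    CrU′ − Cr′; coupling efficiency = (Cr′ − CrO′)/Cr′.  Missing oligomycin or
    FCCP events yield a partial result with the absent fields set to None.  A
    corrected ordering violating CrO′ ≤ Cr′ ≤ CrU′ sets ``quality_flag``.
    """
    t = trace["time_s"].to_numpy(float)
    y = trace.iloc[:, 1].to_numpy(float)
    ev = sorted(events, key=lambda e: e[1])
    times = [e[1] for e in ev]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("event times must be non-decreasing")
    if ev and (times[0] < t[0] or times[-1] > t[-1]):
        raise ValueError("event times must lie within the trace span")

    bounds = times + [float(t[-1]) + 1.0]
    first_event = bounds[0] if ev else float(t[-1]) + 1.0
    cr, cr_sem, _ = _segment_mean(t, y, float(t[0]), first_event, settle_s, plateau_s)

    cro = cro_sem = None
    fccp_means, fccp_sems = [], []
    rox = rox_sem = None
    for i, (label, start) in enumerate(ev):
        stop = bounds[i + 1]
        mean, sem, _ = _segment_mean(t, y, start, stop, settle_s, plateau_s)
        if label == "oligomycin":
            cro, cro_sem = mean, sem
        elif label == "fccp":
            fccp_means.append(mean)
            fccp_sems.append(sem)
        elif label == "inhibitor":
            rox, rox_sem = mean, sem
        else:
            raise ValueError(f"unknown event label {label!r}")

    cru = max(fccp_means) if fccp_means else None
    cru_sem = fccp_sems[int(np.argmax(fccp_means))] if fccp_means else None
    if rox is None:
        rox = 0.0 if rox_constant is None else float(rox_constant)
        if rox_constant is None:
            warnings.warn(
                "no inhibitor event and no ROX constant given; "
                "assuming zero non-mitochondrial respiration", stacklevel=2)

    cr_c = cr - rox
    cro_c = cro - rox if cro is not None else None
    cru_c = cru - rox if cru is not None else None
    spare = cru_c - cr_c if cru_c is not None else None
    coupling = (cr_c - cro_c) / cr_c if (cro_c is not None and cr_c != 0) else None

    ordered = True
    if cro_c is not None and cro_c > cr_c:
        ordered = False
    if cru_c is not None and cru_c < cr_c:
        ordered = False
    if not ordered:
        logger.warning("corrected respiration ordering CrO' <= Cr' <= CrU' violated")

    return {
        "Cr": cr, "CrO": cro, "CrU": cru, "ROX": rox,
        "Cr_corrected": cr_c, "CrO_corrected": cro_c, "CrU_corrected": cru_c,
        "fccp_plateaus": fccp_means,
        "spare_capacity": spare,
        "coupling_efficiency": coupling,
        "sem": {"Cr": cr_sem, "CrO": cro_sem, "CrU": cru_sem, "ROX": rox_sem},
        "quality_flag": not ordered,
    }


def sphere_formation_efficiency(counts: pd.DataFrame, group_by: str = "condition"):
    """Per-well SFE% = 100·spheres/seeded, plus per-condition mean ± SD."""
    if (counts["n_seeded"] <= 0).any():
        raise ValueError("n_seeded must be > 0 in every well")
    if ((counts["n_spheres"] < 0) | (counts["n_spheres"] > counts["n_seeded"])).any():
        raise ValueError("n_spheres must lie in [0, n_seeded]")
    wells = counts.copy()
    wells["sfe_pct"] = 100.0 * wells["n_spheres"] / wells["n_seeded"]
    summary = (
        wells.groupby(group_by)["sfe_pct"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n_wells="count")
        .reset_index()
    )
    return wells, summary


def students_t_test(group_a, group_b) -> dict:
    """Two-tail pooled-variance Student t-test with star annotation.

    Stars: * p<0.05, ** p<0.01, *** p<0.001.  Two identical constant groups
    give t = 0, p = 1; distinct constants with zero variance are an error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must be finite")
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            t_stat, p = 0.0, 1.0
        else:
            raise ValueError("zero pooled variance with unequal means: t undefined")
    else:
        t_stat = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        p = 2.0 * stats.t.sf(abs(t_stat), df)
    stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
    return {"t": float(t_stat), "df": int(df), "p_two_sided": float(p), "stars": stars}
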