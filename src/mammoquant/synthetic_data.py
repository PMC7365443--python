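"""Synthetic-data generators with ground truth for every pipeline stage.

Each generator emulates one instrument output consumed downstream:

* a 4-plex isobaric-reporter peptide table for a paired two-replicate design
  (Control-1 = channel 114, treated-1 = 115, Control-2 = 116, treated-2 = 117),
* NAD(P)H absorbance time courses (lag / linear / saturating-plateau phases),
* high-resolution respirometry (oxygen consumption) traces with bolus events,
* glucose / lactate endpoint panels, and
* per-well sphere counts.

Every generator returns the simulated data together with a truth record so
recovery can be asserted stage by stage.  A single seed fans out to per-entity
substreams through :class:`numpy.random.SeedSequence`, so regenerating a subset
of entities reproduces exactly the same numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ProteomicsSimConfig",
    "TruthTable",
    "generate_itraq_experiment",
    "generate_kinetic_trace",
    "generate_ocr_trace",
    "generate_metabolite_endpoints",
    "generate_sphere_counts",
    "generate_differential_roster",
]


# ---------------------------------------------------------------------------
# configuration / truth containers
# ---------------------------------------------------------------------------

@dataclass
class ProteomicsSimConfig:
    """Parameters of the simulated 4-plex reporter experiment.

    Reporter intensities are log-normal; treatment channels are shifted
    multiplicatively so that for a differential protein ``p``::

        E[log2(i115/i114)] = E[log2(i117/i116)] = null_center + true_log2_effect(p)

    ``peptides_per_protein`` is the mean of a shifted Poisson
    ``1 + Poisson(lambda - 1)``, guaranteeing at least one peptide per protein
    while leaving the >=2-peptide quantitation filter with bite.
    """

    n_proteins: int = 1000
    frac_diff: float = 0.05
    effect_log2_mean: float = 1.0
    effect_log2_sd: float = 0.2
    null_center: float = 0.0
    peptide_noise_sd: float = 0.3
    peptides_per_protein: float = 4.0
    intensity_log_mean: float = np.log(1e4)
    intensity_log_sd: float = 1.0
    ion_score_mean: float = 40.0
    ion_score_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError(f"n_proteins must be >= 1, got {self.n_proteins}")
        if not 0.0 <= self.frac_diff <= 1.0:
            raise ValueError(f"frac_diff must be in [0, 1], got {self.frac_diff}")
        if self.peptide_noise_sd <= 0:
            raise ValueError("peptide_noise_sd must be > 0")
        if self.peptides_per_protein < 1:
            raise ValueError("peptides_per_protein mean must be >= 1")


@dataclass
class TruthTable:
    """Generator-side ground truth for one simulated entity collection."""

    proteins: pd.DataFrame | None = None   # protein_acc, true_log2_effect, direction
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = dict(self.extra)
        if self.proteins is not None:
            out["proteins"] = self.proteins.to_dict(orient="records")
        return out


# ---------------------------------------------------------------------------
# proteomics
# ---------------------------------------------------------------------------

def generate_itraq_experiment(cfg: ProteomicsSimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate a peptide-level 4-plex reporter table with known truth.

    Returns
    -------
    peptides : DataFrame with columns
        ``peptide_id, protein_acc, i114, i115, i116, i117, ion_score,
        identified_at_1pct_fdr``.
    truth : TruthTable with one row per protein
        (``protein_acc, true_log2_effect, direction``).
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_design, rng_pep = (np.random.default_rng(s) for s in ss.spawn(2))

    n = cfg.n_proteins
    n_diff = int(round(cfg.frac_diff * n))
    accs = np.array([f"PROT{i:05d}" for i in range(n)])

    effects = np.zeros(n)
    if n_diff:
        idx = rng_design.choice(n, size=n_diff, replace=False)
        signs = rng_design.choice([-1.0, 1.0], size=n_diff)
        mags = np.abs(rng_design.normal(cfg.effect_log2_mean, cfg.effect_log2_sd, n_diff))
        effects[idx] = signs * mags
    direction = np.where(effects > 0, "up", np.where(effects < 0, "down", "null"))

    lam = max(cfg.peptides_per_protein - 1.0, 0.0)
    n_pep = 1 + rng_design.poisson(lam, size=n)
    total = int(n_pep.sum())

    prot_idx = np.repeat(np.arange(n), n_pep)
    base1 = rng_pep.lognormal(cfg.intensity_log_mean, cfg.intensity_log_sd, total)
    base2 = rng_pep.lognormal(cfg.intensity_log_mean, cfg.intensity_log_sd, total)
    shift = cfg.null_center + effects[prot_idx]
    # ratio noise lives on the treatment channel; log2 ratios then have
    # sd == peptide_noise_sd exactly
    r1 = shift + rng_pep.normal(0.0, cfg.peptide_noise_sd, total)
    r2 = shift + rng_pep.normal(0.0, cfg.peptide_noise_sd, total)

    peptides = pd.DataFrame(
        {
            "peptide_id": [f"PEP{i:06d}" for i in range(total)],
            "protein_acc": accs[prot_idx],
            "i114": base1,
            "i115": base1 * np.exp2(r1),
            "i116": base2,
            "i117": base2 * np.exp2(r2),
            "ion_score": rng_pep.normal(cfg.ion_score_mean, cfg.ion_score_sd, total),
            "identified_at_1pct_fdr": True,
        }
    )
    truth = TruthTable(
        proteins=pd.DataFrame(
            {"protein_acc": accs, "true_log2_effect": effects, "direction": direction}
        ),
        extra={"config": asdict(cfg)},
    )
    return peptides, truth


# ---------------------------------------------------------------------------
# kinetic (absorbance) traces
# ---------------------------------------------------------------------------

def generate_kinetic_trace(
    true_slope: float,
    *,
    lag_s: float = 0.0,
    plateau_onset_s: float | None = None,
    plateau_tau_s: float = 60.0,
    noise_sd: float = 0.0,
    duration_s: float = 600.0,
    dt_s: float = 2.0,
    a0: float = 1.0,
    direction: str | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a 340 nm absorbance trace: lag, linear phase, saturating plateau.

    ``true_slope`` is in absorbance units per **minute** (signed; ``direction``
    only cross-checks the sign when given).  After ``plateau_onset_s`` the rate
    decays exponentially with time constant ``plateau_tau_s`` — the simplest
    smooth approach to substrate depletion.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    if duration_s <= lag_s:
        raise ValueError("duration_s must exceed lag_s")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if direction is not None:
        want = {"increase": 1, "decrease": -1}[direction]
        if true_slope and np.sign(true_slope) != want:
            raise ValueError(f"slope sign contradicts direction={direction!r}")

    t = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    slope_per_s = true_slope / 60.0
    onset = duration_s + 1.0 if plateau_onset_s is None else plateau_onset_s

    lin = np.clip(t - lag_s, 0.0, max(onset - lag_s, 0.0))
    value = a0 + slope_per_s * lin
    past = t > onset
    if past.any():
        # rate decays after onset: integral of slope*exp(-(t-onset)/tau)
        value[past] = (
            a0
            + slope_per_s * max(onset - lag_s, 0.0)
            + slope_per_s * plateau_tau_s * (1.0 - np.exp(-(t[past] - onset) / plateau_tau_s))
        )
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        value = value + rng.normal(0.0, noise_sd, t.size)

    trace = pd.DataFrame({"time_s": t, "value": value})
    truth = {
        "true_slope_per_min": true_slope,
        "lag_s": lag_s,
        "plateau_onset_s": plateau_onset_s,
        "noise_sd": noise_sd,
        "a0": a0,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# respirometry traces
# ---------------------------------------------------------------------------

def generate_ocr_trace(
    levels: dict,
    transition_times: list[float] | None = None,
    *,
    noise_sd: float = 0.0,
    duration_s: float | None = None,
    dt_s: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, float]], dict]:
    """Simulate a piecewise-constant oxygen-consumption trace with bolus events.

    ``levels`` holds ``routine``, ``leak``, ``fccp`` (list, one level per
    uncoupler bolus) and ``nonmito``; ``transition_times`` gives the event
    times (oligomycin, each FCCP bolus, inhibitor) in order.  Omitted segments
    are simply skipped, so ``levels={'routine': x}`` with no transitions yields
    a single flat segment.

    Returns the trace, the event annotation list and a truth dict.  A leak
    level above routine is physically odd but not an error; it is flagged in
    the truth record.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    fccp = list(levels.get("fccp", []))
    seg_levels = [float(levels["routine"])]
    labels: list[str] = []
    if "leak" in levels:
        seg_levels.append(float(levels["leak"]))
        labels.append("oligomycin")
    for lv in fccp:
        seg_levels.append(float(lv))
        labels.append("fccp")
    if "nonmito" in levels:
        seg_levels.append(float(levels["nonmito"]))
        labels.append("inhibitor")
    if any(lv < 0 for lv in seg_levels):
        raise ValueError("all respiration levels must be >= 0")

    n_events = len(labels)
    if transition_times is None:
        transition_times = [120.0 * (i + 1) for i in range(n_events)]
    if len(transition_times) != n_events:
        raise ValueError(
            f"{n_events} transitions implied by levels but {len(transition_times)} times given"
        )
    if any(b <= a for a, b in zip(transition_times, transition_times[1:])):
        raise ValueError("transition times must be strictly increasing")

    if duration_s is None:
        duration_s = (transition_times[-1] + 120.0) if transition_times else 240.0
    t = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    edges = np.array(transition_times, dtype=float)
    seg_idx = np.searchsorted(edges, t, side="right")
    ocr = np.asarray(seg_levels, dtype=float)[seg_idx]
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        ocr = ocr + rng.normal(0.0, noise_sd, t.size)

    events = list(zip(labels, [float(x) for x in transition_times]))
    truth = {
        "segment_levels": seg_levels,
        "segment_labels": ["routine"] + labels,
        "transition_times": list(map(float, transition_times)),
        "noise_sd": noise_sd,
        "leak_exceeds_routine": ("leak" in levels and levels["leak"] > levels["routine"]),
    }
    return pd.DataFrame({"time_s": t, "ocr": ocr}), events, truth


# ---------------------------------------------------------------------------
# metabolite endpoints
# ---------------------------------------------------------------------------

def generate_metabolite_endpoints(
    true_glucose_rate: float,
    true_lactate_rate: float,
    *,
    protein_mg: float = 1.0,
    volume_mL: float = 2.0,
    dt_h: float = 4.0,
    glucose_0: float = 10.0,
    lactate_0: float = 0.5,
    intracellular_lactate_umol: float = 0.1,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a glucose/lactate endpoint panel (µmol/mL at 0 h and ``dt_h``).

    Rates are in µmol·h⁻¹·mg⁻¹ protein; endpoint concentrations receive
    multiplicative log-normal noise of coefficient of variation ``noise_cv``.
    A glucose endpoint driven below zero is floored at 0 and flagged
    ``depleted`` in the truth record.
    """
    if true_glucose_rate < 0 or true_lactate_rate < 0:
        raise ValueError("rates must be >= 0")
    if protein_mg <= 0 or volume_mL <= 0 or dt_h <= 0:
        raise ValueError("protein_mg, volume_mL and dt_h must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")

    g4 = glucose_0 - true_glucose_rate * dt_h * protein_mg / volume_mL
    l4 = lactate_0 + true_lactate_rate * dt_h * protein_mg / volume_mL
    depleted = g4 < 0
    g4 = max(g4, 0.0)

    vals = np.array([glucose_0, g4, lactate_0, l4, intracellular_lactate_umol])
    if noise_cv > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        sigma = np.sqrt(np.log1p(noise_cv**2))       # log-normal with CV=noise_cv, mean 1
        vals = vals * rng.lognormal(-sigma**2 / 2.0, sigma, vals.size)

    panel = pd.DataFrame(
        [
            {
                "glucose_0": vals[0],
                "glucose_4": vals[1],
                "lactate_0": vals[2],
                "lactate_4": vals[3],
                "intracellular_lactate_umol": vals[4],
                "volume_mL": volume_mL,
                "protein_mg": protein_mg,
                "dt_h": dt_h,
            }
        ]
    )
    truth = {
        "true_glucose_rate": true_glucose_rate,
        "true_lactate_rate": true_lactate_rate,
        "depleted": bool(depleted),
    }
    return panel, truth


# ---------------------------------------------------------------------------
# sphere counts
# ---------------------------------------------------------------------------

def generate_sphere_counts(
    n_seeded: int = 2000,
    sfe_true: float = 0.02,
    n_wells: int = 6,
    *,
    condition: str = "control",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-well sphere counts ~ Binomial(n_seeded, sfe_true)."""
    if not 0.0 <= sfe_true <= 1.0:
        raise ValueError("sfe_true must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    counts = rng.binomial(n_seeded, sfe_true, size=n_wells)
    df = pd.DataFrame(
        {
            "well": np.arange(n_wells),
            "condition": condition,
            "n_seeded": n_seeded,
            "n_spheres": counts,
        }
    )
    return df, {"sfe_true": sfe_true, "n_seeded": n_seeded}


# ---------------------------------------------------------------------------
# synthetic differential roster (study-funnel stand-in)
# ---------------------------------------------------------------------------

def generate_differential_roster(
    *,
    n_quantified: int = 2759,
    n_differential: int = 101,
    n_concordant_down: int = 15,
    n_concordant_up: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """SYNTHETIC stand-in for a study-scale protein differential table.

    Builds a protein-level table (per-experiment peptide counts, log2 ratios,
    p and q) whose row-level values carry a realistic filter funnel: of
    ``n_quantified`` proteins quantified with >=2 peptides in both replicate
    experiments, ``n_differential`` reach q < 0.05 in at least one experiment,
    and of those, ``n_concordant_down + n_concordant_up`` reach q < 0.05 in
    BOTH experiments with the same ratio sign.  The defaults mirror the funnel
    a two-replicate isobaric-labelling study of this design produces.  The
    classifier must recover the counts from the rows; nothing downstream reads
    these totals directly.
    """
    n_conc = n_concordant_down + n_concordant_up
    if n_conc > n_differential or n_differential > n_quantified:
        raise ValueError("funnel counts must nest: concordant <= differential <= quantified")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    rows = []

    def q_sig():
        return rng.uniform(1e-4, 0.049)

    def q_ns():
        return rng.uniform(0.06, 1.0)

    def add(i, sign1, sign2, q1, q2):
        r1 = sign1 * rng.uniform(0.4, 2.0) if sign1 else rng.normal(0.0, 0.05)
        r2 = sign2 * rng.uniform(0.4, 2.0) if sign2 else rng.normal(0.0, 0.05)
        rows.append(
            {
                "protein_acc": f"SYN{i:05d}",
                "n_peptides_exp1": int(rng.integers(2, 9)),
                "n_peptides_exp2": int(rng.integers(2, 9)),
                "log2_ratio_exp1": r1,
                "log2_ratio_exp2": r2,
                "q_exp1": q1,
                "q_exp2": q2,
            }
        )

    i = 0
    for _ in range(n_concordant_down):
        add(i, -1, -1, q_sig(), q_sig()); i += 1
    for _ in range(n_concordant_up):
        add(i, +1, +1, q_sig(), q_sig()); i += 1
    # differential but not concordant: significant in one experiment only
    for _ in range(n_differential - n_conc):
        s = int(rng.choice([-1, 1]))
        if rng.random() < 0.5:
            add(i, s, s, q_sig(), q_ns())
        else:
            add(i, s, s, q_ns(), q_sig())
        i += 1
    for _ in range(n_quantified - n_differential):
        add(i, 0, 0, q_ns(), q_ns()); i += 1

    df = pd.DataFrame(rows)
    # p not used by the classifier once q is present; keep q as a stand-in
    df["p_exp1"] = df["q_exp1"]
    df["p_exp2"] = df["q_exp2"]
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
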