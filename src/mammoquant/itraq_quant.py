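"""Differential-abundance statistics for 4-plex isobaric reporter quantitation.

The chain implemented here, in run order:

1. per-peptide log2 reporter ratios for each replicate pair
   (experiment 1: channel 115 over 114; experiment 2: 117 over 116),
2. a Gaussian null ``A·exp(-(x-µ)²/2σ²)`` fitted to the peptide log2-ratio
   histogram by nonlinear least squares — the fitted (µ, σ) absorb any
   systematic labelling/mixing offset and set the ratio noise scale,
3. protein roll-up: median peptide log2 ratio, proteins with fewer than two
   quantitated peptides excluded,
4. z/p against the fitted null with √n_peptides scaling, Benjamini–Hochberg
   quantitation FDR, and
5. a two-tier call: *differential* (q < 0.05 in at least one experiment) and
   *differential_concordant* (q < 0.05 in both experiments AND the same ratio
   sign), the set biological conclusions are drawn from.

All operations work on pandas DataFrames; the peptide schema is the one the
synthetic generator writes (``peptide_id, protein_acc, i114, i115, i116,
i117, ion_score, identified_at_1pct_fdr``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelMap",
    "NullModel",
    "compute_peptide_log2_ratios",
    "fit_gaussian_null",
    "summarize_proteins",
    "protein_pvalues",
    "bh_fdr",
    "classify_differential",
]

EXPERIMENTS = ("exp1", "exp2")

#: default tag assignment: (treatment, control) per replicate experiment
DEFAULT_CHANNEL_MAP = {"exp1": (115, 114), "exp2": (117, 116)}

VALID_CHANNELS = {114, 115, 116, 117}

# Gaussian-fit guard rails: fail loudly rather than fall back to moments
MIN_RATIOS_FOR_FIT = 50
MIN_NONEMPTY_BINS = 10
FIT_TOL = 1e-8
FIT_MAXFEV = 500
#: residual_ss / amplitude² above this marks the fit low-quality (e.g. bimodal input)
LOW_QUALITY_RSS_RATIO = 1.0


@dataclass(frozen=True)
class ChannelMap:
    """Experiment → (treatment_channel, control_channel)."""

    pairs: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))

    def __post_init__(self):
        for exp, (t, c) in self.pairs.items():
            if t == c:
                raise ValueError(f"{exp}: treatment and control channels must differ")
            if t not in VALID_CHANNELS or c not in VALID_CHANNELS:
                raise ValueError(f"{exp}: unknown channel in ({t}, {c}); valid: {sorted(VALID_CHANNELS)}")

    @property
    def experiments(self) -> list[str]:
        return list(self.pairs)


@dataclass
class NullModel:
    """Gaussian fitted to a log2-ratio histogram; the basis of all p-values."""

    mu: float
    sigma: float
    amplitude: float
    bin_edges: np.ndarray
    residual_ss: float
    n_peptides_fit: int
    low_quality: bool = False

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


class GaussianFitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# 1. peptide ratios
# ---------------------------------------------------------------------------

def compute_peptide_log2_ratios(
    peptides: pd.DataFrame, channel_map: ChannelMap | None = None
) -> pd.DataFrame:
    """Per-peptide log2(treatment/control) ratios for each replicate pair.

    Records failing the 1% identification-FDR flag are excluded outright.
    A peptide with a non-positive intensity in a channel required by one
    experiment loses its ratio for that experiment only (NaN); the exclusion
    counts are logged.
    """
    channel_map = channel_map or ChannelMap()
    df = peptides
    if "identified_at_1pct_fdr" in df.columns:
        n_fail = int((~df["identified_at_1pct_fdr"].astype(bool)).sum())
        if n_fail:
            logger.info("excluding %d peptides failing the identification-FDR flag", n_fail)
        df = df[df["identified_at_1pct_fdr"].astype(bool)]

    out = df[["peptide_id", "protein_acc"]].copy()
    for exp, (t, c) in channel_map.pairs.items():
        tcol, ccol = f"i{t}", f"i{c}"
        for col in (tcol, ccol):
            if col not in df.columns:
                raise ValueError(f"channel column {col!r} missing from peptide table")
        ti = df[tcol].to_numpy(float)
        ci = df[ccol].to_numpy(float)
        ok = (ti > 0) & (ci > 0)
        n_drop = int((~ok).sum())
        if n_drop:
            logger.info("%s: dropping %d peptides with non-positive intensities", exp, n_drop)
        ratio = np.full(len(df), np.nan)
        ratio[ok] = np.log2(ti[ok] / ci[ok])
        out[f"ratio_{exp}"] = ratio
    return out


# ---------------------------------------------------------------------------
# 2. Gaussian null
# ---------------------------------------------------------------------------

def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian_null(ratios, n_bins: int = 100, experiment: str = "?") -> NullModel:
    """Least-squares Gaussian fit to the log2-ratio histogram.

    Histogram range is median ± 5·MAD·1.4826 (a robust ±5σ window), split
    into ``n_bins`` equal bins; ``A·exp(-(x-µ)²/2σ²)`` is fitted to the bin
    centers/counts, initialised at (max count, median, 1.4826·MAD).
    Non-convergence or a degenerate width is an error naming the experiment —
    never a silent fall-back to sample moments.
    """
    x = np.asarray(ratios, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < MIN_RATIOS_FOR_FIT:
        raise GaussianFitError(
            f"{experiment}: {x.size} finite ratios < {MIN_RATIOS_FOR_FIT} required for the null fit"
        )
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    robust_sd = 1.4826 * mad
    if robust_sd <= 0:
        raise GaussianFitError(f"{experiment}: zero ratio spread; cannot fit a null")
    lo, hi = med - 5.0 * robust_sd, med + 5.0 * robust_sd
    counts, edges = np.histogram(x[(x >= lo) & (x <= hi)], bins=n_bins, range=(lo, hi))
    if int((counts > 0).sum()) < MIN_NONEMPTY_BINS:
        raise GaussianFitError(
            f"{experiment}: fewer than {MIN_NONEMPTY_BINS} nonempty histogram bins"
        )
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), med, robust_sd)
    try:
        popt, _ = optimize.curve_fit(
            _gauss, centers, counts.astype(float), p0=p0,
            xtol=FIT_TOL, ftol=FIT_TOL, maxfev=FIT_MAXFEV,
        )
    except RuntimeError as e:  # pragma: no cover - solver failure path
        raise GaussianFitError(f"{experiment}: Gaussian fit did not converge: {e}") from e
    a, mu, sigma = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    if sigma <= 0 or not np.isfinite(sigma):
        raise GaussianFitError(f"{experiment}: fitted sigma {sigma} is not positive")
    rss = float(np.sum((counts - _gauss(centers, a, mu, sigma)) ** 2))
    low_quality = rss > LOW_QUALITY_RSS_RATIO * a**2
    if low_quality:
        logger.warning("%s: Gaussian null fit flagged low-quality (rss=%.3g, A=%.3g)",
                       experiment, rss, a)
    return NullModel(
        mu=mu, sigma=sigma, amplitude=a, bin_edges=edges,
        residual_ss=rss, n_peptides_fit=int(x.size), low_quality=low_quality,
    )


# ---------------------------------------------------------------------------
# 3. protein roll-up
# ---------------------------------------------------------------------------

def summarize_proteins(
    ratio_table: pd.DataFrame,
    min_peptides: int = 2,
    experiments=EXPERIMENTS,
) -> pd.DataFrame:
    """Median peptide log2 ratio and peptide count per protein per experiment.

    A protein with fewer than ``min_peptides`` quantitated peptides in an
    experiment carries no ratio there (NaN).
    """
    if ratio_table.empty:
        raise ValueError("ratio table is empty")
    pieces = {}
    for exp in experiments:
        col = f"ratio_{exp}"
        grp = ratio_table.dropna(subset=[col]).groupby("protein_acc")[col]
        agg = grp.agg(n="count", ratio="median")
        agg.loc[agg["n"] < min_peptides, "ratio"] = np.nan
        pieces[exp] = agg
    out = pd.DataFrame(index=sorted(set().union(*(p.index for p in pieces.values()))))
    out.index.name = "protein_acc"
    for exp, agg in pieces.items():
        out[f"n_peptides_{exp}"] = agg["n"].reindex(out.index).fillna(0).astype(int)
        out[f"log2_ratio_{exp}"] = agg["ratio"].reindex(out.index)
    return out.reset_index()


# ---------------------------------------------------------------------------
# 4. p-values and FDR
# ---------------------------------------------------------------------------

def protein_pvalues(
    proteins: pd.DataFrame,
    nulls: dict,
    experiments=EXPERIMENTS,
) -> pd.DataFrame:
    """z and two-sided p for each protein ratio against the fitted null.

    ``z = (log2_ratio − µ) / (σ/√n_peptides)``: the protein median of n
    peptide ratios is scored against a null tightened by √n, so proteins with
    deeper peptide support need smaller shifts to reach significance.
    """
    out = proteins.copy()
    for exp in experiments:
        if exp not in nulls:
            raise KeyError(f"no fitted null model for {exp}")
        null = nulls[exp]
        r = out[f"log2_ratio_{exp}"].to_numpy(float)
        n = out[f"n_peptides_{exp}"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (r - null.mu) / (null.sigma / np.sqrt(n))
        p = 2.0 * stats.norm.sf(np.abs(z))
        out[f"z_{exp}"] = z
        out[f"p_{exp}"] = p
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (NaN-tolerant; NaN stays NaN)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# 5. two-tier differential call
# ---------------------------------------------------------------------------

def classify_differential(
    proteins: pd.DataFrame,
    q_threshold: float = 0.05,
    experiments=EXPERIMENTS,
) -> tuple[pd.DataFrame, dict]:
    """Assign status/direction and count the filter funnel.

    ``differential``: q < threshold in at least one experiment.
    ``differential_concordant``: q < threshold in BOTH experiments and the
    same (nonzero) ratio sign — the set conclusions are drawn from.
    Proteins lacking a quantitation (>=2 peptides) in either experiment are
    ``unquantified``.  If per-experiment q columns are absent they are
    computed from the p columns by Benjamini–Hochberg.
    """
    df = proteins.copy()
    for exp in experiments:
        if f"q_{exp}" not in df.columns:
            df[f"q_{exp}"] = bh_fdr(df[f"p_{exp}"])

    e1, e2 = experiments
    r1 = df[f"log2_ratio_{e1}"].to_numpy(float)
    r2 = df[f"log2_ratio_{e2}"].to_numpy(float)
    q1 = df[f"q_{e1}"].to_numpy(float)
    q2 = df[f"q_{e2}"].to_numpy(float)

    quantified = np.isfinite(r1) & np.isfinite(r2)
    sig1 = quantified & (q1 < q_threshold)
    sig2 = quantified & (q2 < q_threshold)
    differential = sig1 | sig2
    same_sign = (np.sign(r1) == np.sign(r2)) & (np.sign(r1) != 0)
    concordant = sig1 & sig2 & same_sign

    status = np.where(
        ~quantified, "unquantified",
        np.where(concordant, "differential_concordant",
                 np.where(differential, "differential", "not_significant")),
    )
    direction = np.where(concordant & (r1 > 0), "up",
                         np.where(concordant & (r1 < 0), "down", "none"))
    df["status"] = status
    df["direction"] = direction

    funnel = {
        "n_proteins": int(len(df)),
        "n_quantified": int(quantified.sum()),
        "n_differential": int(differential.sum()),
        "n_concordant": int(concordant.sum()),
        "n_up": int((direction == "up").sum()),
        "n_down": int((direction == "down").sum()),
    }
    return df, funnel


# ---------------------------------------------------------------------------
# convenience: the full peptide-table → classified-protein chain
# ---------------------------------------------------------------------------

def quantify(
    peptides: pd.DataFrame,
    channel_map: ChannelMap | None = None,
    *,
    min_peptides: int = 2,
    q_threshold: float = 0.05,
    n_bins: int = 100,
    null_level: str = "peptide",
) -> tuple[pd.DataFrame, dict, dict]:
    """Run ratios → null fit → roll-up → p/q → classification in one call.

    ``null_level`` selects what the Gaussian null is fitted to: ``"peptide"``
    (default; larger n, stabler fit) or ``"protein"`` (median protein ratios,
    the histogram a spreadsheet-level analysis would show).  Returns
    (classified protein table, funnel counts, fitted nulls per experiment).
    """
    channel_map = channel_map or ChannelMap()
    experiments = tuple(channel_map.experiments)
    ratios = compute_peptide_log2_ratios(peptides, channel_map)
    proteins = summarize_proteins(ratios, min_peptides=min_peptides, experiments=experiments)
    if null_level == "peptide":
        nulls = {
            exp: fit_gaussian_null(ratios[f"ratio_{exp}"], n_bins=n_bins, experiment=exp)
            for exp in experiments
        }
    elif null_level == "protein":
        nulls = {
            exp: fit_gaussian_null(proteins[f"log2_ratio_{exp}"], n_bins=n_bins, experiment=exp)
            for exp in experiments
        }
    else:
        raise ValueError(f"null_level must be 'peptide' or 'protein', got {null_level!r}")
    proteins = protein_pvalues(proteins, nulls, experiments=experiments)
    for exp in experiments:
        proteins[f"q_{exp}"] = bh_fdr(proteins[f"p_{exp}"])
    classified, funnel = classify_differential(proteins, q_threshold, experiments=experiments)
    return classified, funnel, nulls
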