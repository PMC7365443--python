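"""Readers/writers, pipeline configuration and the one-command pipeline.

Canonical on-disk formats: tab-separated tables (CSV accepted via ``sep``),
two-column CSV traces with a YAML event sidecar, GMT gene sets, JSON reports.
UTF-8 throughout; missing values are empty fields, never sentinel numbers.
Every report embeds the seed and a hash of the configuration that produced
it, so identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, itraq_quant, synthetic_data
from .enrichment import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "PEPTIDE_COLUMNS",
    "PipelineConfig",
    "read_peptide_table",
    "write_peptide_table",
    "read_gmt",
    "write_gmt",
    "read_trace",
    "write_trace",
    "run_pipeline",
]

PEPTIDE_COLUMNS = ["peptide_id", "protein_acc", "i114", "i115", "i116", "i117", "ion_score"]
_NUMERIC = ["i114", "i115", "i116", "i117", "ion_score"]


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# peptide tables
# ---------------------------------------------------------------------------

def read_peptide_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read and validate a peptide quantitation table.

    Rows with non-numeric intensity/score fields are rejected with their line
    numbers (header = line 1); a summary is logged.  A missing required
    column raises a :class:`SchemaError` naming it.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in PEPTIDE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"peptide table {path} is missing required column {col!r}")
    num = df[_NUMERIC].apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        logger.warning("%s: rejecting %d malformed rows at lines %s",
                       path, int(bad.sum()), lines[:20])
    out = df.loc[~bad, ["peptide_id", "protein_acc"]].copy()
    out[_NUMERIC] = num.loc[~bad]
    if "identified_at_1pct_fdr" in df.columns:
        out["identified_at_1pct_fdr"] = (
            df.loc[~bad, "identified_at_1pct_fdr"].str.lower().isin(["true", "1", "yes"])
        )
    else:
        out["identified_at_1pct_fdr"] = True
    if out.empty:
        logger.warning("%s: no valid peptide rows", path)
    else:
        logger.info("%s: %d peptide rows read", path, len(out))
    return out.reset_index(drop=True)


def write_peptide_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    cols = PEPTIDE_COLUMNS + (
        ["identified_at_1pct_fdr"] if "identified_at_1pct_fdr" in df.columns else []
    )
    df.to_csv(path, sep=sep, index=False, columns=cols)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: name TAB description TAB member...; members deduped."""
    sets: list[GeneSet] = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, desc, *members = parts
            if name in seen:
                raise SchemaError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name=name, description=desc,
                                members=frozenset(m for m in members if m)))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# traces (CSV + YAML event sidecar)
# ---------------------------------------------------------------------------

def write_trace(trace: pd.DataFrame, path, events: list | None = None) -> None:
    trace.to_csv(path, index=False)
    if events is not None:
        side = Path(path).with_suffix(".events.yaml")
        with open(side, "w", encoding="utf-8") as fh:
            yaml.safe_dump([{"label": l, "time_s": t} for l, t in events], fh)


def read_trace(path) -> tuple[pd.DataFrame, list]:
    trace = pd.read_csv(path)
    side = Path(path).with_suffix(".events.yaml")
    events = []
    if side.exists():
        with open(side, encoding="utf-8") as fh:
            events = [(e["label"], float(e["time_s"])) for e in (yaml.safe_load(fh) or [])]
    return trace, events


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the simulate → quant → enrich chain needs."""

    sim: synthetic_data.ProteomicsSimConfig = field(
        default_factory=synthetic_data.ProteomicsSimConfig)
    peptide_table: str | None = None       # read instead of simulating when set
    gmt: str | None = None
    min_peptides: int = 2
    q_threshold: float = 0.05
    null_level: str = "peptide"
    n_perm: int = 1000
    weight_p: float = 1.0
    seed: int = 0
    out_dir: str = "mammoquant_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")
        for p in (self.peptide_table, self.gmt):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = synthetic_data.ProteomicsSimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def hash(self) -> str:
        # fingerprint of the scientific settings only; output location and
        # verbosity do not change results
        payload = {**asdict(self), "sim": asdict(self.sim)}
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Simulate (or read) peptides, quantify, classify, and enrich.

    Writes ``proteins.tsv``, ``enrichment.tsv`` (when a GMT is given) and
    ``funnel.json`` under ``cfg.out_dir`` and returns the report dict.
    """
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if cfg.peptide_table:
        peptides = read_peptide_table(cfg.peptide_table)
        truth = None
    else:
        sim_cfg = synthetic_data.ProteomicsSimConfig(**{**asdict(cfg.sim), "seed": cfg.seed})
        peptides, truth = synthetic_data.generate_itraq_experiment(sim_cfg)

    n_quantifiable = int(
        (peptides["identified_at_1pct_fdr"].astype(bool)
         & (peptides[["i114", "i115", "i116", "i117"]] > 0).all(axis=1)).sum()
    )
    classified, funnel, nulls = itraq_quant.quantify(
        peptides,
        min_peptides=cfg.min_peptides,
        q_threshold=cfg.q_threshold,
        null_level=cfg.null_level,
    )
    classified.to_csv(out_dir / "proteins.tsv", sep="\t", index=False, float_format="%.6g")

    enr_frame = None
    if cfg.gmt:
        ranked = enrichment.rank_proteins(classified)
        results = enrichment.run_gsea(
            ranked, read_gmt(cfg.gmt),
            n_perm=cfg.n_perm, weight_p=cfg.weight_p, seed=cfg.seed,
        )
        enr_frame = enrichment.results_to_frame(results)
        enr_frame.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    report = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "n_identified_quantifiable": n_quantifiable,
        "nulls": {
            exp: {"mu": m.mu, "sigma": m.sigma, "n_peptides_fit": m.n_peptides_fit,
                  "low_quality": m.low_quality}
            for exp, m in nulls.items()
        },
        "funnel": funnel,
    }
    if enr_frame is not None:
        report["enrichment"] = enr_frame.drop(columns=["leading_edge"]).to_dict(orient="records")
    if truth is not None:
        report["truth_n_differential"] = int((truth.proteins["direction"] != "null").sum())
    with open(out_dir / "funnel.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
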