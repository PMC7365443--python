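"""Gene-set enrichment on a ranked protein list (weighted KS running sum).

Proteins are ranked by the mean of their per-experiment log2 ratios; a gene
set is tested for coordinate enrichment/depletion with the weighted
Kolmogorov–Smirnov running-sum statistic: walking the ranked list, each set
member ("hit") increments the sum by ``|score|^p`` normalised over hits and
each non-member decrements it by ``1/(N − n_hits)``; the enrichment score
(ES) is the signed extremum.  Because the underlying design has only two
paired samples, the permutation null resamples random member sets of equal
size from the ranked universe (gene-set permutation); phenotype permutation
is impossible with n = 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .itraq_quant import bh_fdr

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "rank_proteins",
    "enrichment_score",
    "run_gsea",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str = ""
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    es: float
    nes: float
    p_perm: float
    q: float
    leading_edge: list
    degenerate: bool = False


def rank_proteins(proteins: pd.DataFrame, experiments=("exp1", "exp2")) -> pd.DataFrame:
    """Rank by mean per-experiment log2 ratio, descending; ties by accession.

    Only proteins quantified in every experiment are rankable.
    """
    cols = [f"log2_ratio_{e}" for e in experiments]
    df = proteins.dropna(subset=cols)
    if df.empty:
        raise ValueError("no proteins quantified in all experiments; nothing to rank")
    scores = df[cols].mean(axis=1)
    out = pd.DataFrame({"protein_acc": df["protein_acc"].to_numpy(), "score": scores.to_numpy()})
    out = out.sort_values(["score", "protein_acc"], ascending=[False, True], kind="mergesort")
    if out["protein_acc"].duplicated().any():
        raise ValueError("ranked list requires unique accessions")
    return out.reset_index(drop=True)


def _running_sum(scores: np.ndarray, is_hit: np.ndarray, weight_p: float) -> np.ndarray:
    """Vectorised weighted-KS running sum; assumes at least one hit."""
    n = scores.size
    n_hits = int(is_hit.sum())
    w = np.abs(scores) ** weight_p
    hit_norm = w[is_hit].sum()
    steps = np.where(is_hit, np.where(hit_norm > 0, w / max(hit_norm, 1e-300), 0.0), 0.0)
    if n_hits < n:
        steps = steps - np.where(is_hit, 0.0, 1.0 / (n - n_hits))
    return np.cumsum(steps)


def enrichment_score(
    ranked: pd.DataFrame, gene_set: GeneSet, weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES (signed extremum of the running sum) and the full running sum.

    Raises if the set has no member in the ranked list.  A set covering the
    whole list is degenerate (the sum never decrements); it is computed with a
    zero miss-penalty and flagged by the caller.
    """
    accs = ranked["protein_acc"].to_numpy()
    scores = ranked["score"].to_numpy(float)
    is_hit = np.isin(accs, list(gene_set.members))
    if not is_hit.any():
        raise ValueError(f"set {gene_set.name!r} not represented in the ranked list")
    rs = _running_sum(scores, is_hit, weight_p)
    es = float(np.clip(rs[np.argmax(np.abs(rs))], -1.0, 1.0))
    return es, rs


def _leading_edge(ranked: pd.DataFrame, is_hit: np.ndarray, rs: np.ndarray, es: float) -> list:
    accs = ranked["protein_acc"].to_numpy()
    peak = int(np.argmax(np.abs(rs)))
    if es >= 0:
        sel = is_hit & (np.arange(accs.size) <= peak)
    else:
        sel = is_hit & (np.arange(accs.size) >= peak)
    return accs[sel].tolist()


def run_gsea(
    ranked: pd.DataFrame,
    gene_sets: list,
    *,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Score each gene set with a gene-set permutation null.

    For each set of overlap k, ``n_perm`` random k-subsets of the ranked
    universe give null ES values; ``p_perm = (1 + #{|null| >= |ES|}) /
    (1 + n_perm)`` (never exactly zero) and ``NES = ES / mean(|null ES| of
    matching sign)``.  q across sets by Benjamini–Hochberg.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    accs = ranked["protein_acc"].to_numpy()
    scores = ranked["score"].to_numpy(float)
    n = accs.size
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    results = []
    for gs in gene_sets:
        is_hit = np.isin(accs, list(gs.members))
        k = int(is_hit.sum())
        if k == 0:
            raise ValueError(f"set {gs.name!r} not represented in the ranked list")
        if k > n:
            raise ValueError(f"set {gs.name!r} larger than the ranked universe")
        degenerate = k == n
        rs = _running_sum(scores, is_hit, weight_p)
        es = float(np.clip(rs[np.argmax(np.abs(rs))], -1.0, 1.0))

        null_es = np.empty(n_perm)
        for b in range(n_perm):
            perm_hit = np.zeros(n, dtype=bool)
            perm_hit[rng.choice(n, size=k, replace=False)] = True
            nrs = _running_sum(scores, perm_hit, weight_p)
            null_es[b] = nrs[np.argmax(np.abs(nrs))]

        p_perm = (1.0 + np.count_nonzero(np.abs(null_es) >= abs(es))) / (1.0 + n_perm)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null_es).mean()
        nes = float(es / denom) if denom > 0 else float("nan")
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                overlap=k,
                es=es,
                nes=nes,
                p_perm=float(p_perm),
                q=np.nan,
                leading_edge=_leading_edge(ranked, is_hit, rs, es),
                degenerate=degenerate,
            )
        )

    qs = bh_fdr([r.p_perm for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate EnrichmentResults (leading edge joined with ';')."""
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "overlap": [r.overlap for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_perm": [r.p_perm for r in results],
            "q": [r.q for r in results],
            "leading_edge": [";".join(r.leading_edge) for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
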