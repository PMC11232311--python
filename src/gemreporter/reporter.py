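"""Reporter-metabolite scoring.

A metabolite's neighbor genes are the genes in the rules of the reactions
it participates in.  Each gene's (mode-transformed) p-value becomes a
normal score Z_g = Phi^-1(1 - p_g); a metabolite with k neighbor genes is
scored by the Stouffer aggregate

    z_raw = sum(Z_g) / sqrt(k)

and corrected against a size-matched background: mu_k and sigma_k are the
mean and SD of the same aggregate over random k-gene draws from all scored
model genes, so

    z_corrected = (z_raw - mu_k) / sigma_k,   p = 1 - Phi(z_corrected).

Sampling the background from the observed gene-score population (rather
than assuming standard-normal gene scores) keeps the statistic calibrated
when the input p-values are not uniform.  Directional modes rescore genes
one-sidedly: ``up`` maps a two-sided p to p/2 for up-regulated genes and
1 - p/2 for down-regulated ones; ``down`` mirrors this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .model import MetabolicModel

__all__ = [
    "GeneScoreMap",
    "BackgroundNull",
    "ReporterRecord",
    "neighbor_genes",
    "directional_pvalues",
    "reporter_scores",
    "significant_reporters",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

P_CLIP = 1e-15
SIGMA_FLOOR = 1e-12
MODES = ("all", "up", "down")


@dataclass
class GeneScoreMap:
    p: dict[str, float]
    mode: str


@dataclass
class BackgroundNull:
    """Monte-Carlo null moments of the aggregate per gene-set size k."""

    mu: dict[int, float]
    sigma: dict[int, float]
    n_draws: int


@dataclass
class ReporterRecord:
    metabolite: str
    compartment: str
    k: int
    z_raw: float
    z_corrected: float
    p_reporter: float
    mode: str


def neighbor_genes(model: MetabolicModel, metabolite: str) -> set[str]:
    """Genes of all reactions the (compartment-specific) metabolite joins.

    Gene rules are flattened: AND/OR structure is ignored, every gene in the
    rule counts as a neighbor.
    """
    if metabolite not in model.metabolites:
        raise KeyError(f"metabolite {metabolite!r} not in model")
    out: set[str] = set()
    for rxn in model.reactions.values():
        if metabolite in rxn.stoichiometry:
            out |= rxn.genes
    return out


def directional_pvalues(deg: pd.DataFrame, mode: str = "all",
                        restrict_alpha: float | None = None) -> GeneScoreMap:
    """Per-gene scoring p-values for a directional mode.

    ``all``: two-sided p unchanged.  ``up``: p/2 when log2fc > 0 else
    1 - p/2 (evidence against up-regulation).  ``down``: mirrored.  A zero
    fold change in a directional mode scores 0.5 (no direction) and is
    logged.  Outputs are clipped to [P_CLIP, 1 - P_CLIP] so gene Z-scores
    stay finite.

    When ``restrict_alpha`` is given, the one-sided transform is replaced
    by a restriction: only genes with two-sided p < restrict_alpha (and, in
    a directional mode, the matching fold-change sign) are scored, with
    their p left untouched.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    out: dict[str, float] = {}
    for _, row in deg.iterrows():
        gene, p, fc = str(row["gene"]), float(row["p"]), float(row["log2fc"])
        if restrict_alpha is not None:
            if p >= restrict_alpha:
                continue
            if mode == "up" and fc <= 0:
                continue
            if mode == "down" and fc >= 0:
                continue
            out[gene] = float(np.clip(p, P_CLIP, 1 - P_CLIP))
            continue
        if mode == "all":
            q = p
        elif fc == 0.0:
            logger.info("directional_pvalues: %s has log2fc == 0 in %s mode; "
                        "scored 0.5", gene, mode)
            q = 0.5
        elif (fc > 0) == (mode == "up"):
            q = p / 2
        else:
            q = 1 - p / 2
        out[gene] = float(np.clip(q, P_CLIP, 1 - P_CLIP))
    return GeneScoreMap(out, mode)


def reporter_scores(model: MetabolicModel,
                    scores: GeneScoreMap,
                    n_background: int = 10000,
                    seed: int | np.random.Generator = 0,
                    ) -> tuple[list[ReporterRecord], BackgroundNull]:
    """Score every metabolite with at least one scored neighbor gene.

    The background universe is the intersection of scored genes with the
    model's gene set; metabolites are scored over their scored neighbors
    only.  Records are sorted by ascending p_reporter (ties by id).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    universe = sorted(set(scores.p) & model.genes)
    if not universe:
        raise ValueError("no scored gene occurs in the model")
    z_by_gene = {g: float(ndtri(1.0 - np.clip(scores.p[g], P_CLIP, 1 - P_CLIP)))
                 for g in universe}
    z_pop = np.array([z_by_gene[g] for g in universe])

    met_neighbors: dict[str, list[str]] = {}
    for mid in model.metabolites:
        genes = sorted(g for g in neighbor_genes(model, mid) if g in z_by_gene)
        if genes:
            met_neighbors[mid] = genes

    sizes = sorted({len(g) for g in met_neighbors.values()})
    null = _background_null(z_pop, sizes, n_background, rng)

    records = []
    for mid, genes in met_neighbors.items():
        k = len(genes)
        z_raw = float(sum(z_by_gene[g] for g in genes) / np.sqrt(k))
        z_corr = (z_raw - null.mu[k]) / null.sigma[k]
        p_rep = float(ndtr(-z_corr))  # upper tail of z_corrected
        records.append(ReporterRecord(
            metabolite=mid, compartment=model.metabolites[mid].compartment,
            k=k, z_raw=z_raw, z_corrected=float(z_corr), p_reporter=p_rep,
            mode=scores.mode))
    records.sort(key=lambda r: (r.p_reporter, r.metabolite))
    return records, null


def _background_null(z_pop: np.ndarray, sizes: list[int],
                     n_draws: int, rng: np.random.Generator) -> BackgroundNull:
    n_genes = len(z_pop)
    mu, sigma = {}, {}
    for k in sizes:
        if k > n_genes:
            raise ValueError(
                f"gene-set size {k} exceeds the scored gene universe "
                f"({n_genes} genes)")
        if k == n_genes:
            draws = np.full(n_draws, z_pop.sum() / np.sqrt(k))
        else:
            # n_draws index sets of size k without replacement within a draw
            keys = rng.random((n_draws, n_genes))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            draws = z_pop[idx].sum(axis=1) / np.sqrt(k)
        mu[k] = float(draws.mean())
        s = float(draws.std(ddof=0))
        if s < SIGMA_FLOOR:
            logger.warning("background sigma for k=%d below floor; "
                           "all gene scores may be identical", k)
            s = SIGMA_FLOOR
        sigma[k] = s
    return BackgroundNull(mu, sigma, n_draws)


def significant_reporters(records: list[ReporterRecord],
                          alpha: float = 0.1) -> list[ReporterRecord]:
    """Records with p_reporter strictly below alpha, order preserved."""
    return [r for r in records if r.p_reporter < alpha]


def records_to_frame(records: list[ReporterRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "metabolite": r.metabolite, "compartment": r.compartment, "k": r.k,
        "z_raw": r.z_raw, "z_corrected": r.z_corrected,
        "p_reporter": r.p_reporter, "mode": r.mode,
    } for r in records], columns=["metabolite", "compartment", "k", "z_raw",
                                  "z_corrected", "p_reporter", "mode"])
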