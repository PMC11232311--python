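"""Expression-tier classification and reaction weighting.

Genes are partitioned into HIGH / MEDIUM / LOW / ABSENT tiers against the
quartiles of the pooled expression distribution of the whole matrix (all
gene × sample values, not per-gene): a gene is ABSENT when it falls below
the pooled lower quartile in more than a configurable fraction of samples
(default 80%), and otherwise tiered by its maximum expression relative to
the pooled quartiles.  Evidence from a differential-expression table or a
detected-protein list can force genes to HIGH regardless of tier.  Tier
scores are pushed through each reaction's gene rule (OR -> max, AND -> min)
to produce the per-reaction weights consumed by context-specific model
extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gpr import evaluate_gpr
from .model import MetabolicModel

__all__ = [
    "TIERS",
    "DEFAULT_TIER_SCORES",
    "GeneExpressionClass",
    "classify_genes",
    "combine_cohorts",
    "force_high",
    "reaction_weights",
    "read_expression",
    "read_deg_table",
]

logger = logging.getLogger(__name__)

TIERS = ("HIGH", "MEDIUM", "LOW", "ABSENT")
_TIER_ORDER = {t: i for i, t in enumerate(TIERS)}  # 0 = highest

#: Default tier scores for reaction weighting.  Magnitudes are chosen so a
#: single HIGH gene cannot outweigh two ABSENT ones in a summed objective.
DEFAULT_TIER_SCORES = {"HIGH": 5.0, "MEDIUM": 1.0, "LOW": -2.0, "ABSENT": -8.0}


@dataclass
class GeneExpressionClass:
    """Per-gene expression tier with provenance.

    provenance is one of ``quartile`` (derived from the expression matrix),
    ``forced_deg`` or ``forced_protein`` (forced to HIGH by external
    evidence).
    """

    tier: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def set(self, gene: str, tier: str, provenance: str) -> None:
        if tier not in TIERS:
            raise ValueError(f"unknown tier {tier!r}")
        self.tier[gene] = tier
        self.provenance[gene] = provenance

    def counts(self) -> dict[str, int]:
        out = {t: 0 for t in TIERS}
        for t in self.tier.values():
            out[t] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.tier)
        return pd.DataFrame({
            "gene": genes,
            "tier": [self.tier[g] for g in genes],
            "provenance": [self.provenance[g] for g in genes],
        })


def read_expression(path: str) -> pd.DataFrame:
    """Read a genes × samples TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dupes[:5]}")
    return df


def read_deg_table(path: str) -> pd.DataFrame:
    """Read a differential-expression TSV with gene/log2fc/p/p_adj columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "p", "p_adj"}
    if not required <= set(df.columns):
        raise ValueError(f"DEG table {path} missing columns "
                         f"{sorted(required - set(df.columns))}")
    return df


def classify_genes(expr: pd.DataFrame,
                   absent_sample_frac: float = 0.80,
                   q_low: float = 0.25,
                   q_high: float = 0.75) -> GeneExpressionClass:
    """Tier genes against pooled quartiles of the full expression matrix.

    Parameters
    ----------
    expr : DataFrame, genes × samples, log-scale intensities.
    absent_sample_frac : a gene is ABSENT iff its value is strictly below
        the pooled ``q_low`` quantile in strictly more than this fraction
        of its samples.
    q_low, q_high : pooled quantiles (linear-interpolation estimator)
        separating LOW / MEDIUM / HIGH by the gene's maximum expression.
    """
    if expr.empty:
        raise ValueError("empty expression matrix")
    if not 0 < q_low < q_high < 1:
        raise ValueError("require 0 < q_low < q_high < 1")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    pooled = values.ravel()
    lo, hi = np.quantile(pooled, [q_low, q_high])  # type-7 linear
    if lo == hi:
        raise ValueError(
            "degenerate expression matrix: pooled quantiles coincide "
            f"(Q{q_low}=Q{q_high}={lo})")
    below_frac = (values < lo).mean(axis=1)
    gmax = values.max(axis=1)
    classes = GeneExpressionClass()
    for gene, frac, mx in zip(expr.index, below_frac, gmax):
        if frac > absent_sample_frac:
            tier = "ABSENT"
        elif mx > hi:
            tier = "HIGH"
        elif mx > lo:
            tier = "MEDIUM"
        else:
            tier = "LOW"
        classes.set(str(gene), tier, "quartile")
    return classes


def combine_cohorts(*cohorts: GeneExpressionClass) -> GeneExpressionClass:
    """Combine per-cohort classifications by tier maximum (HIGH wins).

    Cohorts are classified independently — expression values are never
    averaged across cohorts — and a gene's combined tier is its best tier
    in any cohort.
    """
    out = GeneExpressionClass()
    for classes in cohorts:
        for gene, tier in classes.tier.items():
            prev = out.tier.get(gene)
            if prev is None or _TIER_ORDER[tier] < _TIER_ORDER[prev]:
                out.set(gene, tier, classes.provenance[gene])
    return out


def force_high(classes: GeneExpressionClass,
               deg: pd.DataFrame | None = None,
               p_adj_force: float = 0.001,
               proteins: list[str] | None = None) -> GeneExpressionClass:
    """Force strongly differentially expressed / detected-protein genes HIGH.

    Genes with ``p_adj < p_adj_force`` in the DEG table and genes on the
    detected-protein list become HIGH with forced provenance; genes not yet
    classified are added as HIGH (expressed evidence from another assay) and
    logged.  Idempotent.
    """
    out = GeneExpressionClass(dict(classes.tier), dict(classes.provenance))
    forced: list[tuple[str, str]] = []
    if deg is not None and len(deg):
        hits = deg.loc[deg["p_adj"] < p_adj_force, "gene"]
        forced += [(str(g), "forced_deg") for g in hits]
    for g in proteins or ():
        forced.append((str(g), "forced_protein"))
    for gene, prov in forced:
        if gene not in out.tier:
            logger.info("force_high: gene %s absent from classification, "
                        "added as HIGH (%s)", gene, prov)
        out.set(gene, "HIGH", prov)
    return out


def reaction_weights(model: MetabolicModel,
                     classes: GeneExpressionClass,
                     tier_scores: dict[str, float] | None = None,
                     ) -> dict[str, float]:
    """Per-reaction expression weight from gene tiers through the gene rule.

    OR (isozymes) takes the max of its branches, AND (complex) the min.
    Genes missing from ``classes`` count as ABSENT; reactions with an empty
    gene rule get weight 0.
    """
    scores = dict(DEFAULT_TIER_SCORES if tier_scores is None else tier_scores)
    missing = set(TIERS) - set(scores)
    if missing:
        raise ValueError(f"tier_scores missing tiers {sorted(missing)}")

    def gene_score(gene: str) -> float:
        return scores[classes.tier.get(gene, "ABSENT")]

    return {rid: evaluate_gpr(rxn.gene_rule, gene_score, empty_value=0.0)
            for rid, rxn in model.reactions.items()}
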