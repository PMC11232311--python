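"""Synthetic study generator.

Emulates the statistical structure of a two-group (IPH− vs IPH+ plaque)
multi-omics study on a compartmentalized toy metabolic network:

* a toy GEM spanning cytosol, mitochondria and the extracellular space,
  built from parallel linear pathways plus a glutamate/glutamine core —
  glutamine synthetase (GLUL), glutaminase (GLS) and the cytosol↔
  mitochondria glutamate carrier (SLC25A12/SLC25A13) — with a planted
  high-connectivity hub metabolite (cytosolic glutamate) bridging the two
  compartments, currency metabolites, and exchange reactions that make the
  network flux-consistent;
* two-cohort log-scale expression with the hub's enzyme genes up-shifted
  in the case group, and a t-test/BH differential-expression table;
* batch-structured metabolomics with pooled-QC samples, multiplicative
  batch factors, completely-at-random missingness and planted abundance
  shifts concentrated in one metabolite category.

Every output is deterministic under the scenario seed, and the truth
record carries everything needed to score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import MetabolicModel, Metabolite, Reaction

__all__ = ["SyntheticScenario", "generate_toy_model", "generate_expression",
           "generate_metabolomics"]

HUB_ID = "glutamate[c]"


@dataclass
class SyntheticScenario:
    """Defaults mirror the study design: two phenotype groups, two
    transcriptomics cohorts, three metabolomics batches with pooled QC."""

    seed: int = 0
    # network
    n_pathways: int = 6
    pathway_size: tuple[int, int] = (4, 7)
    hub_degree: int = 8               # reactions incident to the hub
    # expression effect
    delta: float = 2.0                # planted log2 shift on hub genes
    sigma: float = 1.0                # per-gene noise SD (log scale)
    affected_frac: float = 1.0        # fraction of hub-adjacent genes shifted
    n_background_genes: int = 200     # non-metabolic genes on the array
    cohort_sizes: tuple[int, int] = (20, 20)   # per-group n, primary cohort
    second_cohort_n: int = 40                  # unlabeled replication cohort
    # metabolomics
    n_metabolomics: int = 109
    n_batches: int = 3
    n_primary: int = 35
    n_qc: int = 11
    missing_rate: float = 0.05
    met_shift_fold: float = 2.0
    enriched_category: str = "sphingolipid"
    enriched_category_size: int = 20
    enriched_category_shifted: int = 14
    batch_factors: tuple[float, ...] = (1.0, 1.3, 0.8)

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def _chain_met(p: int, i: int, comp: str = "c") -> str:
    return f"pw{p}_m{i}[{comp}]"


def generate_toy_model(scenario: SyntheticScenario) -> tuple[MetabolicModel, dict]:
    """Build the compartmentalized toy GEM; returns (model, truth record).

    The glutamate core reactions use the HMR identifiers and stoichiometries
    of the corresponding human reactions; extra hub reactions attach
    cytosolic glutamate to the parallel pathways (transaminase-style) until
    the hub reaches the requested degree.
    """
    sc = scenario
    rng = sc.rng(1)
    model = MetabolicModel(id="toy_gem")

    def met(mid, name="", is_currency=False, category=None):
        if mid not in model.metabolites:
            model.add_metabolite(Metabolite(id=mid, name=name or mid.rsplit("[", 1)[0],
                                            is_currency=is_currency,
                                            category=category))

    def rxn(rid, stoich, reversible=False, gene_rule="", subsystem=None):
        model.add_reaction(Reaction(id=rid, stoichiometry=stoich,
                                    reversible=reversible,
                                    gene_rule=gene_rule, subsystem=subsystem))

    # currency metabolites
    for name in ("ATP", "ADP", "Pi", "H2O", "H+", "CoA", "NAD+", "NADH"):
        met(f"{name}[c]", name, is_currency=True)
    met("H+[m]", "H+", is_currency=True)
    met("H+[s]", "H+", is_currency=True)
    met("H2O[s]", "H2O", is_currency=True)

    # glutamate/glutamine core (cytosol + mitochondria + exchange)
    for mid, cat in (("glutamate[c]", "amino acid"), ("glutamate[m]", "amino acid"),
                     ("glutamine[c]", "amino acid"), ("glutamine[s]", "amino acid"),
                     ("glutamate[s]", "amino acid"), ("NH3[c]", "other"),
                     ("NH3[s]", "other"), ("aspartate[c]", "amino acid"),
                     ("aspartate[m]", "amino acid"), ("aspartate[s]", "amino acid"),
                     ("AKG[m]", "organic acid"), ("AKG[c]", "organic acid"),
                     ("AKG[s]", "organic acid"),
                     ("oxaloacetate[c]", "organic acid"),
                     ("oxaloacetate[s]", "organic acid")):
        met(mid, category=cat)

    rxn("HMR_3890", {"ATP[c]": -1, "NH3[c]": -1, "glutamate[c]": -1,
                     "ADP[c]": 1, "Pi[c]": 1, "glutamine[c]": 1},
        gene_rule="GLUL", subsystem="glutamate metabolism")
    rxn("HMR_9802", {"H2O[c]": -1, "glutamine[c]": -1,
                     "NH3[c]": 1, "glutamate[c]": 1},
        gene_rule="GLS", subsystem="glutamate metabolism")
    rxn("HMR_3825", {"H+[c]": -1, "aspartate[m]": -1, "glutamate[c]": -1,
                     "H+[m]": 1, "aspartate[c]": 1, "glutamate[m]": 1},
        gene_rule="SLC25A12 or SLC25A13", subsystem="transport, mitochondrial")
    rxn("T_GLU", {"glutamate[s]": -1, "glutamate[c]": 1}, gene_rule="SLC1A3")
    rxn("T_GLN", {"glutamine[c]": -1, "glutamine[s]": 1}, gene_rule="SLC38A1")
    rxn("T_NH3", {"NH3[c]": -1, "NH3[s]": 1}, reversible=True)
    rxn("T_ASP", {"aspartate[s]": -1, "aspartate[c]": 1}, gene_rule="SLC1A2")
    rxn("T_ASPM", {"aspartate[c]": -1, "aspartate[m]": 1}, gene_rule="SLC25A13")
    rxn("GDH_M", {"glutamate[m]": -1, "NAD+[c]": -1,
                  "AKG[m]": 1, "NADH[c]": 1, "NH3[c]": 1},
        gene_rule="GLUD1", subsystem="glutamate metabolism")
    rxn("T_AKG", {"AKG[m]": -1, "AKG[c]": 1}, gene_rule="SLC25A11")
    rxn("T_AKGS", {"AKG[c]": -1, "AKG[s]": 1}, reversible=True)
    rxn("ATP_REGEN", {"ADP[c]": -1, "Pi[c]": -1, "ATP[c]": 1, "H2O[c]": 1},
        gene_rule="ATPGEN1")
    rxn("NADH_OX", {"NADH[c]": -1, "NAD+[c]": 1, "H+[c]": 1}, gene_rule="NOX1")
    rxn("H_LEAK", {"H+[m]": -1, "H+[c]": 1}, reversible=True)
    rxn("T_H", {"H+[c]": -1, "H+[s]": 1}, reversible=True)
    rxn("T_H2O", {"H2O[c]": -1, "H2O[s]": 1}, reversible=True)
    # transamination gives aspartate a sink and feeds cytosolic glutamate
    rxn("AST_C", {"aspartate[c]": -1, "AKG[c]": -1,
                  "oxaloacetate[c]": 1, "glutamate[c]": 1},
        gene_rule="GOT1", subsystem="glutamate metabolism")
    rxn("T_OAA", {"oxaloacetate[c]": -1, "oxaloacetate[s]": 1})
    for mid in ("glutamate[s]", "glutamine[s]", "NH3[s]", "aspartate[s]",
                "AKG[s]", "H2O[s]", "H+[s]", "oxaloacetate[s]"):
        rxn(f"EX_{mid.rsplit('[', 1)[0]}", {mid: -1}, reversible=True)

    # parallel pathways, cytosolic chains fed and drained extracellularly
    categories = ("sphingolipid", "glycerophospholipid", "sugar",
                  "cholesterol derivative", "organic acid", "amino acid")
    gene_counter = 0
    chain_mets: list[str] = []
    for p in range(sc.n_pathways):
        length = int(rng.integers(sc.pathway_size[0], sc.pathway_size[1] + 1))
        cat = categories[p % len(categories)]
        first_s = f"pw{p}_m0[s]"
        met(first_s, category=cat)
        rxn(f"EX_pw{p}_in", {first_s: -1}, reversible=True)
        prev = first_s
        for i in range(1, length + 1):
            mid = _chain_met(p, i)
            met(mid, category=cat)
            chain_mets.append(mid)
            gene_counter += 1
            genes = [f"PWG{gene_counter}"]
            if rng.random() < 0.4:
                gene_counter += 1
                genes.append(f"PWG{gene_counter}")
                rule = " or ".join(genes) if rng.random() < 0.5 \
                    else " and ".join(genes)
            else:
                rule = genes[0]
            rxn(f"R_pw{p}_{i}", {prev: -1, mid: 1}, gene_rule=rule,
                subsystem=f"pathway {p} ({cat})")
            prev = mid
        last_s = f"pw{p}_mend[s]"
        met(last_s, category=cat)
        rxn(f"R_pw{p}_out", {prev: -1, last_s: 1})
        rxn(f"EX_pw{p}_out", {last_s: -1}, reversible=True)

    # extra hub reactions: transaminase-style taps into the pathways
    core_hub_rxns = ["HMR_3890", "HMR_9802", "HMR_3825", "T_GLU", "AST_C"]
    n_extra = sc.hub_degree - len(core_hub_rxns)
    if n_extra < 0:
        raise ValueError("hub_degree smaller than the fixed glutamate core")
    if n_extra > len(chain_mets) // 2:
        raise ValueError("hub_degree too large for the generated pathways")
    picks = rng.choice(len(chain_mets) // 2, size=n_extra, replace=False)
    hub_genes = {"GLUL", "GLS", "SLC25A12", "SLC25A13", "SLC1A3", "GOT1"}
    for j, pick in enumerate(sorted(picks)):
        a = chain_mets[2 * pick]
        b = chain_mets[2 * pick + 1]
        gene = f"HUBG{j + 1}"
        hub_genes.add(gene)
        rxn(f"R_hub_{j + 1}", {"glutamate[c]": -1, a: -1, "AKG[c]": 1, b: 1},
            gene_rule=gene, subsystem="hub transamination")

    truth = {"hub": HUB_ID, "hub_genes": sorted(hub_genes),
             "seed": sc.seed, "n_reactions": model.n_reactions,
             "n_metabolites": model.n_metabolites}
    return model, truth


def generate_expression(model: MetabolicModel, scenario: SyntheticScenario,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Two cohort expression matrices, a DEG table and the truth record.

    The primary cohort carries the group contrast (planted genes shifted by
    ``delta`` in the case group); the second cohort is unlabeled and feeds
    only the tier classification.  The DEG table comes from per-gene
    two-sample t-tests with BH adjustment — a generator-internal
    convenience standing in for a full microarray DEG workflow, since
    downstream stages only consume (gene, log2fc, p, p_adj).
    """
    sc = scenario
    rng = sc.rng(2)
    model_genes = sorted(model.genes)
    extra = [f"BG{i}" for i in range(sc.n_background_genes)]
    genes = model_genes + extra
    _, truth_model = generate_toy_model(sc)
    hub_genes = [g for g in truth_model["hub_genes"] if g in model.genes]
    n_aff = max(1, int(round(sc.affected_frac * len(hub_genes))))
    planted = sorted(rng.choice(hub_genes, size=n_aff, replace=False).tolist())

    baselines = rng.uniform(4.0, 12.0, size=len(genes))
    n1, n2 = sc.cohort_sizes
    cols = [f"ctrl_{i}" for i in range(n1)] + [f"case_{i}" for i in range(n2)]
    values = baselines[:, None] + rng.normal(0, sc.sigma,
                                             size=(len(genes), n1 + n2))
    planted_idx = [genes.index(g) for g in planted]
    values[planted_idx, n1:] += sc.delta
    primary = pd.DataFrame(values, index=genes, columns=cols)

    cols2 = [f"rep_{i}" for i in range(sc.second_cohort_n)]
    values2 = baselines[:, None] + rng.normal(
        0, sc.sigma, size=(len(genes), sc.second_cohort_n))
    second = pd.DataFrame(values2, index=genes, columns=cols2)

    ctrl = primary.iloc[:, :n1].to_numpy()
    case = primary.iloc[:, n1:].to_numpy()
    tt = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
    deg = pd.DataFrame({
        "gene": genes,
        "log2fc": case.mean(axis=1) - ctrl.mean(axis=1),
        "p": tt.pvalue,
    })
    deg["p_adj"] = multipletests(deg["p"], method="fdr_bh")[1]

    truth = {"planted_genes": planted, "hub": truth_model["hub"],
             "delta": sc.delta, "sigma": sc.sigma, "seed": sc.seed}
    return primary, second, deg, truth


def generate_metabolomics(model: MetabolicModel, scenario: SyntheticScenario,
                          ) -> tuple["object", dict[str, str], dict]:
    """Batch-structured metabolomics matrix, category map and truth record.

    Log-normal abundances with per-batch multiplicative factors; QC samples
    are drawn around the pooled mean of each metabolite; planted shifts
    multiply the case group by ``met_shift_fold`` and are concentrated in
    one category so the enrichment test has a recoverable signal.
    Missingness is injected completely at random.
    """
    from .metabolomics import MetabolomicsMatrix

    sc = scenario
    rng = sc.rng(3)
    model_named = [m for m in model.metabolites.values()
                   if m.compartment == "c" and not m.is_currency]
    names, cats = [], {}
    for m in model_named:
        base = m.id.rsplit("[", 1)[0]
        if base not in cats:
            names.append(base)
            cats[base] = m.category or "other"
    i = 0
    while len(names) < sc.n_metabolomics:
        names.append(f"met_x{i}")
        i += 1
    names = names[: sc.n_metabolomics]

    # force one category to the configured size, then fill the rest
    pool = ("glycerophospholipid", "sugar", "cholesterol derivative",
            "organic acid", "amino acid", "other")
    unassigned = [n for n in names if n not in cats]
    rng.shuffle(unassigned)
    n_enriched_have = sum(1 for n in names
                          if cats.get(n) == sc.enriched_category)
    need = sc.enriched_category_size - n_enriched_have
    for n in unassigned[:max(need, 0)]:
        cats[n] = sc.enriched_category
    for j, n in enumerate(unassigned[max(need, 0):]):
        cats[n] = pool[j % len(pool)]
    categories = {n: cats[n] for n in names}

    # planted shifts: most in the enriched category, a few elsewhere
    enriched = [n for n in names if categories[n] == sc.enriched_category]
    shifted = sorted(rng.choice(enriched,
                                size=min(sc.enriched_category_shifted,
                                         len(enriched)),
                                replace=False).tolist())
    others = [n for n in names if categories[n] != sc.enriched_category]
    shifted += sorted(rng.choice(others, size=min(3, len(others)),
                                 replace=False).tolist())

    n_case = sc.n_primary // 2
    n_ctrl = sc.n_primary - n_case
    sample_ids, batch, stype, group = [], [], [], []
    for i in range(n_ctrl):
        sample_ids.append(f"P{i:02d}")
        group.append("IPH-")
    for i in range(n_case):
        sample_ids.append(f"P{n_ctrl + i:02d}")
        group.append("IPH+")
    stype += ["primary"] * sc.n_primary
    for i in range(sc.n_qc):
        sample_ids.append(f"QC{i:02d}")
        stype.append("QC")
        group.append("none")
    order = rng.permutation(len(sample_ids))
    batches = [f"B{1 + (k * sc.n_batches) // len(sample_ids)}"
               for k in range(len(sample_ids))]
    batch_of = {sample_ids[order[k]]: batches[k]
                for k in range(len(sample_ids))}
    # guarantee each batch holds at least one QC sample by moving spares
    qc_ids = [s for s, t in zip(sample_ids, stype) if t == "QC"]
    all_batches = [f"B{b + 1}" for b in range(sc.n_batches)]
    if sc.n_qc < sc.n_batches:
        raise ValueError("need at least one QC sample per batch")
    qc_in = {b: [q for q in qc_ids if batch_of[q] == b] for b in all_batches}
    for b in all_batches:
        if not qc_in[b]:
            donor = max(qc_in, key=lambda x: len(qc_in[x]))
            moved = qc_in[donor].pop()
            batch_of[moved] = b
            qc_in[b].append(moved)

    samples = pd.DataFrame({
        "batch": [batch_of[s] for s in sample_ids],
        "sample_type": stype,
        "group": group,
    }, index=sample_ids)

    log_mu = rng.uniform(2.0, 4.0, size=len(names))     # log10 abundance
    log_sd = 0.15
    factors = {b: sc.batch_factors[i % len(sc.batch_factors)]
               for i, b in enumerate(all_batches)}
    values = np.zeros((len(names), len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        is_qc = stype[j] == "QC"
        noise_sd = 0.05 if is_qc else log_sd
        v = 10 ** (log_mu + rng.normal(0, noise_sd, size=len(names)))
        if not is_qc and group[j] == "IPH+":
            for i_m, nme in enumerate(names):
                if nme in shifted:
                    v[i_m] *= sc.met_shift_fold
        values[:, j] = v * factors[batch_of[sid]]
    mask = rng.random(values.shape) < sc.missing_rate
    values = values.astype(float)
    values[mask] = np.nan
    matrix = MetabolomicsMatrix(
        pd.DataFrame(values, index=names, columns=sample_ids), samples)
    truth = {"shifted_metabolites": shifted,
             "enriched_category": sc.enriched_category,
             "batch_factors": factors, "seed": sc.seed}
    return matrix, categories, truth
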