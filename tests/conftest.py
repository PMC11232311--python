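import numpy as np
import pandas as pd
import pytest

from gemreporter.model import MetabolicModel, Metabolite, Reaction

GLU_FIXTURE_METS = [
    ("ATP[c]", True), ("ADP[c]", True), ("Pi[c]", True), ("H2O[c]", True),
    ("H+[c]", True), ("H+[m]", True), ("NH3[c]", False),
    ("glutamate[c]", False), ("glutamate[m]", False), ("glutamine[c]", False),
    ("aspartate[c]", False), ("aspartate[m]", False),
]


@pytest.fixture
def glu_fixture_model() -> MetabolicModel:
    """Three-reaction glutamate/glutamine fixture: glutamine synthetase,
    glutaminase and the mitochondrial aspartate-glutamate carrier."""
    m = MetabolicModel(id="glu_fixture")
    for mid, cur in GLU_FIXTURE_METS:
        m.add_metabolite(Metabolite(id=mid, is_currency=cur))
    m.add_reaction(Reaction(
        id="HMR_3890",
        stoichiometry={"ATP[c]": -1, "NH3[c]": -1, "glutamate[c]": -1,
                       "ADP[c]": 1, "Pi[c]": 1, "glutamine[c]": 1},
        gene_rule="GLUL"))
    m.add_reaction(Reaction(
        id="HMR_9802",
        stoichiometry={"H2O[c]": -1, "glutamine[c]": -1,
                       "NH3[c]": 1, "glutamate[c]": 1},
        gene_rule="GLS"))
    m.add_reaction(Reaction(
        id="HMR_3825",
        stoichiometry={"H+[c]": -1, "aspartate[m]": -1, "glutamate[c]": -1,
                       "H+[m]": 1, "aspartate[c]": 1, "glutamate[m]": 1},
        gene_rule="SLC25A12 or SLC25A13"))
    return m


def make_chain_model(n: int = 2, reversible_exchange: bool = True,
                     dead_end: bool = False) -> MetabolicModel:
    """Linear chain A0[s] -> A1[c] -> ... -> An[s] with exchanges at the ends;
    optionally a dead-end reaction producing an orphan metabolite."""
    m = MetabolicModel(id="chain")
    m.add_metabolite(Metabolite(id="A0[s]"))
    for i in range(1, n):
        m.add_metabolite(Metabolite(id=f"A{i}[c]"))
    m.add_metabolite(Metabolite(id=f"A{n}[s]"))
    ids = ["A0[s]"] + [f"A{i}[c]" for i in range(1, n)] + [f"A{n}[s]"]
    m.add_reaction(Reaction(id="EX_in", stoichiometry={"A0[s]": -1},
                            reversible=reversible_exchange))
    for i in range(n):
        m.add_reaction(Reaction(id=f"R{i}",
                                stoichiometry={ids[i]: -1, ids[i + 1]: 1}))
    m.add_reaction(Reaction(id="EX_out", stoichiometry={ids[-1]: -1},
                            reversible=reversible_exchange))
    if dead_end:
        m.add_metabolite(Metabolite(id="orphan[c]"))
        m.add_reaction(Reaction(id="R_dead",
                                stoichiometry={ids[1]: -1, "orphan[c]": 1}))
    return m


@pytest.fixture(scope="session")
def synthetic_null_reporter_pvals() -> np.ndarray:
    """Reporter p-values pooled over 20 seeded runs on a >=100-metabolite
    synthetic model with uniform gene p-values (the global null)."""
    from gemreporter.reporter import directional_pvalues, reporter_scores
    from gemreporter.synth import SyntheticScenario, generate_toy_model

    pooled = []
    for seed in range(20):
        scenario = SyntheticScenario(seed=seed, n_pathways=18,
                                     pathway_size=(5, 8))
        model, _ = generate_toy_model(scenario)
        assert model.n_metabolites >= 100
        rng = np.random.default_rng(1000 + seed)
        genes = sorted(model.genes)
        deg = pd.DataFrame({
            "gene": genes,
            "log2fc": rng.normal(size=len(genes)),
            "p": rng.uniform(size=len(genes)),
        })
        records, _ = reporter_scores(model, directional_pvalues(deg, "all"),
                                     n_background=10000, seed=seed)
        pooled.extend(r.p_reporter for r in records)
    return np.asarray(pooled)


def random_toy_model(rng: np.random.Generator, n_mets: int = 6,
                     n_rxns: int = 10) -> MetabolicModel:
    """Random cytosolic conversion network with exchanges on every
    extracellular terminal, for flux-consistency oracles."""
    m = MetabolicModel(id="random_toy")
    m.add_metabolite(Metabolite(id="S[s]"))
    m.add_metabolite(Metabolite(id="P[s]"))
    for i in range(n_mets):
        m.add_metabolite(Metabolite(id=f"M{i}[c]"))
    m.add_reaction(Reaction(id="EX_S", stoichiometry={"S[s]": -1},
                            reversible=True))
    m.add_reaction(Reaction(id="EX_P", stoichiometry={"P[s]": -1},
                            reversible=True))
    m.add_reaction(Reaction(id="UP", stoichiometry={"S[s]": -1, "M0[c]": 1}))
    m.add_reaction(Reaction(
        id="SEC", stoichiometry={f"M{n_mets - 1}[c]": -1, "P[s]": 1}))
    for j in range(n_rxns):
        a, b = rng.choice(n_mets, size=2, replace=False)
        m.add_reaction(Reaction(
            id=f"R{j}", stoichiometry={f"M{a}[c]": -1, f"M{b}[c]": 1},
            reversible=bool(rng.random() < 0.3)))
    return m
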