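"""Metabolomics validation arm: QC filtering, batch correction,
differential abundance and category permutation enrichment.

The data model is a metabolite × sample abundance matrix (missing values
as NaN) with three per-sample attributes: ``batch``, ``sample_type``
(``QC`` for pooled quality-control injections, ``primary`` otherwise) and
``group`` (the two phenotype labels for primary samples, ``none`` for QC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetabolomicsMatrix",
    "read_metabolomics",
    "write_metabolomics",
    "read_categories",
    "qc_filter",
    "batch_correct",
    "differential_abundance",
    "category_permutation_test",
]

logger = logging.getLogger(__name__)

SAMPLE_ATTRS = ("batch", "sample_type", "group")


@dataclass
class MetabolomicsMatrix:
    """Abundances (metabolites × samples) plus per-sample attributes."""

    values: pd.DataFrame
    samples: pd.DataFrame  # index = sample ids; columns = SAMPLE_ATTRS

    def __post_init__(self):
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample attribute rows do not match the "
                             "abundance matrix columns")
        missing = set(SAMPLE_ATTRS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample attributes missing {sorted(missing)}")
        st = self.samples["sample_type"]
        if not st.isin(["QC", "primary"]).all():
            raise ValueError("sample_type must be 'QC' or 'primary'")
        grp = self.samples["group"].astype(str)
        bad_qc = (st == "QC") & ~grp.isin(["none", "nan", ""])
        if bad_qc.any():
            raise ValueError("QC samples must have group 'none'")
        if ((st == "primary") & grp.isin(["none", "nan", ""])).any():
            raise ValueError("every primary sample needs a group label")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative abundances")

    @property
    def qc_columns(self) -> list[str]:
        return list(self.samples.index[self.samples["sample_type"] == "QC"])

    @property
    def primary_columns(self) -> list[str]:
        return list(self.samples.index[self.samples["sample_type"] == "primary"])

    def group_columns(self, group: str) -> list[str]:
        mask = (self.samples["sample_type"] == "primary") \
            & (self.samples["group"] == group)
        return list(self.samples.index[mask])

    def copy(self) -> "MetabolomicsMatrix":
        return MetabolomicsMatrix(self.values.copy(), self.samples.copy())


def write_metabolomics(m: MetabolomicsMatrix, path: str) -> None:
    """TSV with a 3-row sample-attribute header (#batch/#sample_type/#group)."""
    with open(path, "w", encoding="utf-8") as fh:
        cols = list(m.values.columns)
        fh.write("metabolite\t" + "\t".join(cols) + "\n")
        for attr in SAMPLE_ATTRS:
            vals = [str(m.samples.loc[c, attr]) for c in cols]
            fh.write(f"#{attr}\t" + "\t".join(vals) + "\n")
        for met, row in m.values.iterrows():
            cells = ["" if pd.isna(v) else repr(float(v)) for v in row]
            fh.write(str(met) + "\t" + "\t".join(cells) + "\n")


def read_metabolomics(path: str) -> MetabolomicsMatrix:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    attr_rows = [f"#{a}" for a in SAMPLE_ATTRS]
    for r in attr_rows:
        if r not in raw.index:
            raise ValueError(f"{path}: missing attribute row {r!r}")
    samples = pd.DataFrame(
        {a: raw.loc[f"#{a}"] for a in SAMPLE_ATTRS})
    samples.index.name = None
    values = raw.drop(index=attr_rows).replace("", np.nan).astype(float)
    values.index.name = None
    values.columns.name = None
    return MetabolomicsMatrix(values, samples)


def read_categories(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["metabolite"], df["category"]))


def qc_filter(m: MetabolomicsMatrix,
              max_missing_frac: float = 0.20,
              max_rsd: float = 0.50) -> tuple[MetabolomicsMatrix, pd.DataFrame]:
    """Drop unreliable metabolites; returns (filtered matrix, exclusion log).

    A metabolite is excluded if it is undetected (missing) in more than
    ``max_missing_frac`` of all samples, or if its relative standard
    deviation (SD/mean) over the pooled-QC samples exceeds ``max_rsd``.
    The two rules are independent, so their order does not matter; the log
    records every rule each excluded metabolite violated.
    """
    qc_cols = m.qc_columns
    if not qc_cols:
        logger.warning("qc_filter: no QC samples; RSD rule skipped")
    log_rows = []
    keep = []
    for met, row in m.values.iterrows():
        rules = []
        miss = float(row.isna().mean())
        if miss > max_missing_frac:
            rules.append("missingness")
        rsd = np.nan
        if qc_cols:
            qc = row[qc_cols].dropna()
            if len(qc) >= 2 and qc.mean() != 0:
                rsd = float(qc.std(ddof=1) / qc.mean())
                if rsd > max_rsd:
                    rules.append("rsd")
        if rules:
            log_rows.append({"metabolite": met, "rule": "+".join(rules),
                             "missing_frac": miss, "qc_rsd": rsd})
        else:
            keep.append(met)
    log = pd.DataFrame(log_rows,
                       columns=["metabolite", "rule", "missing_frac", "qc_rsd"])
    return MetabolomicsMatrix(m.values.loc[keep], m.samples.copy()), log


def batch_correct(m: MetabolomicsMatrix,
                  mode: str = "multiplicative") -> MetabolomicsMatrix:
    """Synchronize per-batch QC medians to the global QC median.

    For each metabolite and batch, all values in the batch are scaled by
    (global QC median / batch QC median) — or shifted by the difference in
    ``additive`` mode — so that afterwards every batch's QC median equals
    the global one.  Idempotent; a single batch is returned unchanged.
    Metabolites whose batch QC median is zero (multiplicative mode) or
    whose QC values are all missing in some batch are flagged and left
    uncorrected.
    """
    if mode not in ("multiplicative", "additive"):
        raise ValueError("mode must be 'multiplicative' or 'additive'")
    batches = m.samples["batch"].unique()
    if len(batches) <= 1:
        return m.copy()
    qc = set(m.qc_columns)
    if not qc:
        raise ValueError("batch_correct requires QC samples")
    out = m.values.copy()
    batch_cols = {b: list(m.samples.index[m.samples["batch"] == b])
                  for b in batches}
    for b, cols in batch_cols.items():
        if not set(cols) & qc:
            raise ValueError(f"batch {b!r} has no QC sample")
    for met, row in m.values.iterrows():
        global_med = row[list(qc & set(m.values.columns))].median()
        corrected = row.copy()
        ok = True
        for b, cols in batch_cols.items():
            qc_vals = row[[c for c in cols if c in qc]].dropna()
            if qc_vals.empty:
                ok = False
                break
            med = qc_vals.median()
            if mode == "multiplicative":
                if med == 0:
                    ok = False
                    break
                corrected[cols] = row[cols] * (global_med / med)
            else:
                corrected[cols] = row[cols] + (global_med - med)
        if ok:
            out.loc[met] = corrected
        else:
            logger.warning("batch_correct: %s left uncorrected "
                           "(zero or missing batch QC median)", met)
    return MetabolomicsMatrix(out, m.samples.copy())


def _two_sample_p(x: np.ndarray, y: np.ndarray,
                  shapiro_alpha: float = 0.05,
                  test: str = "auto") -> tuple[float, str]:
    """Normality-gated two-sample test: Student's t if both groups pass
    Shapiro–Wilk at ``shapiro_alpha``, else two-sided Wilcoxon rank-sum
    (exact when both n <= 25 and tie-free, normal approximation with tie
    correction otherwise).  ``test`` forces a branch when not 'auto'."""
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0, "degenerate"

    def normal(v: np.ndarray) -> bool:
        if np.ptp(v) == 0:
            return False  # constant group: Shapiro undefined, not normal
        return stats.shapiro(v).pvalue >= shapiro_alpha

    if test == "t" or (test == "auto" and normal(x) and normal(y)):
        return float(stats.ttest_ind(x, y, equal_var=True).pvalue), "t"
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue), "wilcoxon"


def differential_abundance(m: MetabolomicsMatrix,
                           alpha_adj: float = 0.1,
                           groups: tuple[str, str] = ("IPH-", "IPH+"),
                           test: str = "auto") -> pd.DataFrame:
    """Per-metabolite dysregulation calls between the two phenotype groups.

    ``groups`` orders (reference, case); direction is the sign of
    (case median − reference median).  Missing values are dropped pairwise;
    metabolites with fewer than 3 observed values in either group are not
    tested.  P-values are BH-adjusted across all tested metabolites and a
    metabolite is called up/down when adjusted p < ``alpha_adj``.
    """
    ref_cols = m.group_columns(groups[0])
    case_cols = m.group_columns(groups[1])
    rows = []
    for met, row in m.values.iterrows():
        y = row[ref_cols].dropna().to_numpy(dtype=float)
        x = row[case_cols].dropna().to_numpy(dtype=float)
        if len(x) < 3 or len(y) < 3:
            logger.warning("differential_abundance: %s skipped "
                           "(n=%d vs %d)", met, len(x), len(y))
            continue
        p, used = _two_sample_p(x, y, test=test)
        rows.append({"metabolite": met, "n_ref": len(y), "n_case": len(x),
                     "test": used, "p": p,
                     "median_diff": float(np.median(x) - np.median(y))})
    calls = pd.DataFrame(rows, columns=["metabolite", "n_ref", "n_case",
                                        "test", "p", "median_diff"])
    if calls.empty:
        calls["p_adj"] = []
        calls["call"] = []
        return calls.set_index("metabolite")
    calls["p_adj"] = multipletests(calls["p"], method="fdr_bh")[1]
    direction = np.where(calls["median_diff"] > 0, "up",
                         np.where(calls["median_diff"] < 0, "down",
                                  "unchanged"))
    calls["call"] = np.where(calls["p_adj"] < alpha_adj, direction,
                             "unchanged")
    return calls.set_index("metabolite")


def category_permutation_test(calls: pd.DataFrame,
                              categories: dict[str, str],
                              direction: str = "up",
                              n_perm: int = 100000,
                              seed: int | np.random.Generator = 0,
                              ) -> pd.DataFrame:
    """Permutation enrichment of dysregulated metabolites per category.

    The statistic for a category is the number of its members called in
    the given direction.  The null permutes the call vector across all
    tested metabolites with category membership fixed (equivalent, under
    exchangeability, to resampling category labels).  Reported with the
    add-one correction, p = (1 + #{null >= observed}) / (1 + n_perm) for
    over-representation and the mirrored tail for under-representation.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mets = list(calls.index)
    hit = (calls["call"] == direction).to_numpy()
    cat_members: dict[str, np.ndarray] = {}
    for cat in sorted(set(categories.values())):
        idx = np.array([i for i, met in enumerate(mets)
                        if categories.get(met) == cat], dtype=int)
        if len(idx) == 0:
            logger.warning("category %r has no tested member; skipped", cat)
            continue
        cat_members[cat] = idx

    perms = np.tile(hit, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    rows = []
    for cat, idx in cat_members.items():
        observed = int(hit[idx].sum())
        null_counts = perms[:, idx].sum(axis=1)
        p_over = (1 + int((null_counts >= observed).sum())) / (1 + n_perm)
        p_under = (1 + int((null_counts <= observed).sum())) / (1 + n_perm)
        rows.append({"category": cat, "n_in_category": len(idx),
                     "n_dysregulated_in_category": observed,
                     "direction": direction,
                     "p_perm": p_over, "p_perm_under": p_under,
                     "n_perm": n_perm})
    return pd.DataFrame(rows, columns=[
        "category", "n_in_category", "n_dysregulated_in_category",
        "direction", "p_perm", "p_perm_under", "n_perm"])
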