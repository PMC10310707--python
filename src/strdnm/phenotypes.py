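"""Parental transmitted-mDNM phenotypes and gene-level enrichment testing.

The phenotype for a parent is the number of de novo events that parent
transmitted, corrected for nuisance covariates and normalized for use in
quantitative-trait association:

1. per parent-offspring pair, residualize the count on parental age at the
   offspring's conception, parental sex, sequencing method, sample type
   and the trio's available-marker count (ordinary least squares);
2. average the residuals over each parent's offspring;
3. rank-based inverse-normal transform (Blom offset 3/8) to an
   approximately standard-normal scale.

The enrichment test asks whether exonic variants in a candidate gene carry
more nominal (p < 0.05) association signals than expected: after randomly
pruning one member of each variant pair in strong LD (r^2 > 0.9), the
number of nominal variants among N is compared to Binomial(N, 0.05),
one-sided, with a Bonferroni correction over genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_COVARIATES = ("parent_age", "parent_sex", "seq_method", "sample_type", "m_t")
CATEGORICAL_COVARIATES = ("parent_sex", "seq_method", "sample_type")


def residualize_counts(
    rows: pd.DataFrame,
    count_col: str = "count",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.Series:
    """OLS residuals of per-offspring parental mDNM counts on covariates.

    Categorical covariates are dummy-coded; aliased (rank-deficient)
    columns are dropped by the pseudo-inverse fit with a warning.
    Residuals sum to ~0 by construction.
    """
    if len(rows) < 10:
        raise ValueError("need at least 10 rows to residualize")
    used = [c for c in covariates if c in rows.columns]
    parts = []
    for c in used:
        if c in CATEGORICAL_COVARIATES or rows[c].dtype == object:
            parts.append(pd.get_dummies(rows[c], prefix=c, drop_first=True, dtype=float))
        else:
            parts.append(rows[[c]].astype(float))
    X = sm.add_constant(pd.concat(parts, axis=1)) if parts else pd.DataFrame(
        {"const": np.ones(len(rows))}, index=rows.index
    )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        import warnings

        warnings.warn("rank-deficient covariate design; aliased columns absorbed")
    res = sm.OLS(rows[count_col].astype(float), X).fit()
    return res.resid.rename("residual")


def aggregate_per_parent(rows: pd.DataFrame, value_col: str = "residual") -> pd.Series:
    """Mean residual per parent (parents with several offspring are averaged)."""
    return rows.groupby("parent_id")[value_col].mean()


def rank_inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-based inverse-normal transform.

    value_i = Phi^-1((r_i - c) / (n + 1 - 2c)) with 1-based average ranks
    r_i and c = 3/8, giving an approximately standard-normal phenotype.
    Strictly monotone where there are no ties; all-identical input maps to
    all zeros with a warning.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 values for rank inverse normalization")
    if np.ptp(values) == 0:
        import warnings

        warnings.warn("all values identical; transformed phenotype is all zeros")
        return np.zeros(n)
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - offset) / (n + 1 - 2 * offset))


def build_parent_offspring_rows(
    phased_calls: pd.DataFrame,
    trios: pd.DataFrame,
    allocation: str = "phased",
) -> pd.DataFrame:
    """One covariate row per parent-offspring pair from phased calls.

    The count attributed to a parent is the consensus-phased count
    (``allocation='phased'``, default); with ``allocation='proportional'``
    unphased events are additionally split between the parents in
    proportion to their phased counts (falling back to an even split for
    trios with no phased events).
    """
    if allocation not in ("phased", "proportional"):
        raise ValueError("allocation must be 'phased' or 'proportional'")
    counts = (
        phased_calls.groupby(["child_id", "phase"]).size().unstack(fill_value=0)
        if not phased_calls.empty
        else pd.DataFrame()
    )
    for col in ("paternal", "maternal", "unknown"):
        if col not in counts.columns:
            counts[col] = 0
    counts = counts.reindex(trios["child_id"]).fillna(0)
    y_p = counts["paternal"].to_numpy(dtype=float)
    y_m = counts["maternal"].to_numpy(dtype=float)
    if allocation == "proportional":
        y_u = counts["unknown"].to_numpy(dtype=float)
        phased = y_p + y_m
        share = np.where(phased > 0, y_p / np.where(phased > 0, phased, 1.0), 0.5)
        y_p = y_p + y_u * share
        y_m = y_m + y_u * (1.0 - share)
    rows = []
    for i, trio in enumerate(trios.itertuples(index=False)):
        common = {
            "offspring_id": trio.child_id,
            "m_t": trio.m_t,
            "seq_method": getattr(trio, "seq_method", "wgs"),
            "sample_type": getattr(trio, "sample_type", "blood"),
        }
        rows.append(
            {
                **common,
                "parent_id": trio.father_id,
                "parent_sex": "M",
                "parent_age": trio.father_age,
                "count": y_p[i],
            }
        )
        rows.append(
            {
                **common,
                "parent_id": trio.mother_id,
                "parent_sex": "F",
                "parent_age": trio.mother_age,
                "count": y_m[i],
            }
        )
    return pd.DataFrame(rows)


def build_parent_phenotypes(
    rows: pd.DataFrame,
    count_col: str = "count",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Full pipeline: residualize -> average per parent -> rank-INT."""
    out = rows.copy()
    out["residual"] = residualize_counts(out, count_col, covariates)
    per_parent = aggregate_per_parent(out).reset_index()
    per_parent["phenotype"] = rank_inverse_normal(per_parent["residual"].to_numpy())
    return per_parent[["parent_id", "residual", "phenotype"]]


def prune_ld(
    variants: pd.DataFrame,
    ld_pairs: pd.DataFrame,
    r2_threshold: float = 0.9,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Randomly drop one member of each variant pair with r^2 above threshold.

    Pairs are visited in seeded random order; a pair both of whose members
    survive so far loses one member at random (greedy pruning).
    """
    rng = np.random.default_rng(seed)
    keep = set(variants["variant_id"])
    strong = ld_pairs[ld_pairs["r2"] > r2_threshold]
    order = strong.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31)))
    for row in order.itertuples(index=False):
        if row.variant_a in keep and row.variant_b in keep:
            keep.discard(row.variant_a if rng.random() < 0.5 else row.variant_b)
    return variants[variants["variant_id"].isin(keep)]


def enrichment_test(
    variants: pd.DataFrame,
    ld_pairs: pd.DataFrame | None = None,
    p_threshold: float = 0.05,
    r2_threshold: float = 0.9,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-gene binomial enrichment of nominal association p-values.

    ``variants`` columns: variant_id, gene, p_value.  Returns per gene the
    post-pruning variant count N, the nominal count k, the one-sided
    binomial p-value for k successes in N at rate ``p_threshold``, and a
    Bonferroni-corrected significance flag.
    """
    pruned = (
        prune_ld(variants, ld_pairs, r2_threshold, seed)
        if ld_pairs is not None and not ld_pairs.empty
        else variants
    )
    rows = []
    for gene, grp in pruned.groupby("gene"):
        n = len(grp)
        if n == 0:
            continue
        k = int((grp["p_value"] < p_threshold).sum())
        p = stats.binomtest(k, n, p_threshold, alternative="greater").pvalue
        rows.append({"gene": gene, "n_variants": n, "n_nominal": k, "enrichment_p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        n_genes = len(out)
        out["bonferroni_significant"] = out["enrichment_p"] < 0.05 / n_genes
    return out
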