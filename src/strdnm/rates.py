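"""Mutation-rate estimation and related cohort summaries.

The per-motif-length mDNM rate is r_i = D_i / T_i where D_i counts de novo
calls at markers with motif length i and T_i counts marker-trio tests
(the sum over trios of eligible markers of that length); units are
mutations per microsatellite per generation.  The genome-wide expected
number of mDNMs per offspring extrapolates the per-length rates to the
full microsatellite census:  E[mDNMs] = sum_i r_i * n_i.  Confidence
intervals come from a percentile bootstrap over microsatellites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

TOTAL_MICROSATELLITES = 1_394_292  # genome-wide polymorphic STR census


def estimate_rates(calls: pd.DataFrame, eligibility: pd.DataFrame) -> pd.DataFrame:
    """Per-motif-length mDNM rates plus an 'all' row.

    ``eligibility``: one row per (trio, motif length) with ``n_eligible``.
    Lengths with zero tests are omitted with a warning.
    """
    tests = eligibility.groupby("motif_length")["n_eligible"].sum()
    dnms = (
        calls.groupby("motif_length").size()
        if not calls.empty
        else pd.Series(dtype=int)
    )
    table = pd.DataFrame({"tests": tests}).fillna(0)
    table["dnms"] = dnms.reindex(table.index).fillna(0).astype(int)
    zero = table["tests"] == 0
    if zero.any():
        import warnings

        warnings.warn(
            f"motif lengths {sorted(table.index[zero])} have no eligible tests; omitted"
        )
        table = table[~zero]
    table["rate"] = table["dnms"] / table["tests"]
    total = pd.DataFrame(
        {
            "tests": [table["tests"].sum()],
            "dnms": [table["dnms"].sum()],
            "rate": [table["dnms"].sum() / table["tests"].sum()],
        },
        index=pd.Index(["all"], name="motif_length"),
    )
    return pd.concat([table, total]).reset_index()


def bootstrap_rate_ci(
    marker_table: pd.DataFrame,
    n_replicates: int = 100,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> dict:
    """Percentile bootstrap CI for the overall mDNM rate.

    ``marker_table`` has one row per microsatellite with ``tested_trios``
    (number of trios available for detection there) and ``dnm_count``.
    Markers are resampled with replacement; the rate sum(dnms)/sum(tests)
    is recomputed per replicate and the (alpha/2, 1-alpha/2) quantiles
    reported.  The point estimate is always returned alongside.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    tests = marker_table["tested_trios"].to_numpy(dtype=float)
    dnms = marker_table["dnm_count"].to_numpy(dtype=float)
    n = len(tests)
    point = dnms.sum() / tests.sum()
    if n == 1:
        import warnings

        warnings.warn("single-marker input: bootstrap CI degenerates to the point estimate")
        return {"rate": point, "ci_low": point, "ci_high": point, "replicates": None}
    idx = rng.integers(0, n, size=(n_replicates, n))
    reps = dnms[idx].sum(axis=1) / tests[idx].sum(axis=1)
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return {"rate": point, "ci_low": float(lo), "ci_high": float(hi), "replicates": reps}


def extrapolate_expected(
    rate_table: pd.DataFrame,
    genomewide_counts: dict[int, int],
    exclude_homopolymers: bool = False,
) -> float:
    """E[mDNMs per offspring] = sum_i r_i * n_i over included motif lengths."""
    total = 0.0
    for row in rate_table.itertuples(index=False):
        if row.motif_length == "all":
            continue
        i = int(row.motif_length)
        if exclude_homopolymers and i == 1:
            continue
        if i not in genomewide_counts:
            raise KeyError(f"no genome-wide microsatellite count for motif length {i}")
        total += row.rate * genomewide_counts[i]
    return total


def _merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    merged = []
    for chrom, grp in intervals.sort_values(["chrom", "start"]).groupby("chrom"):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def annotation_overrepresentation(
    calls: pd.DataFrame, annotation: pd.DataFrame, total_span: int
) -> dict:
    """Density odds ratio of mDNMs inside vs outside annotated intervals.

    OR = (mDNMs_in / bp_in) / (mDNMs_out / bp_out).  A call is inside if
    its marker start lies in a (merged, half-open) interval.  With no
    outside calls the OR is infinite; zero annotated bp is an error.
    """
    merged = _merge_intervals(annotation)
    bp_in = int((merged["end"] - merged["start"]).sum())
    if bp_in == 0:
        raise ValueError("annotation spans zero bp")
    if total_span <= bp_in:
        raise ValueError("total span must exceed the annotated span")
    bp_out = total_span - bp_in
    n_in = 0
    for chrom, grp in merged.groupby("chrom"):
        sub = calls[calls["chrom"] == chrom]
        if sub.empty:
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        pos = sub["start"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        inside = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        n_in += int(inside.sum())
    n_out = len(calls) - n_in
    odds_in = n_in / bp_in
    odds_out = n_out / bp_out
    ratio = np.inf if n_out == 0 else odds_in / odds_out
    return {
        "mdnms_in": n_in,
        "bp_in": bp_in,
        "mdnms_out": n_out,
        "bp_out": bp_out,
        "odds_ratio": ratio,
    }


def attribute_regression(
    marker_table: pd.DataFrame,
    attributes: tuple[str, ...] = ("motif_length", "rrt_length", "gc_content", "purity"),
    by_motif_length: bool = False,
) -> pd.DataFrame:
    """Poisson log-linear regression of per-marker mDNM counts on attributes.

    Uses log(tested trios) as offset, so coefficients act on the per-trio
    rate.  Returns coefficient estimates with Wald standard errors and
    p-values, overall or stratified by motif length.
    """

    def _fit(df: pd.DataFrame, cols: tuple[str, ...], stratum) -> pd.DataFrame:
        X = sm.add_constant(df[list(cols)].astype(float))
        offset = np.log(df["tested_trios"].astype(float))
        model = sm.GLM(
            df["dnm_count"].astype(float), X, family=sm.families.Poisson(), offset=offset
        )
        try:
            res = model.fit()
        except Exception as exc:  # separation / non-convergence
            return pd.DataFrame(
                [{"stratum": stratum, "term": "error", "estimate": np.nan, "note": str(exc)}]
            )
        out = pd.DataFrame(
            {
                "term": res.params.index,
                "estimate": res.params.to_numpy(),
                "std_err": res.bse.to_numpy(),
                "p_value": res.pvalues.to_numpy(),
            }
        )
        out.insert(0, "stratum", stratum)
        return out

    if not by_motif_length:
        return _fit(marker_table, attributes, "all")
    cols = tuple(a for a in attributes if a != "motif_length")
    pieces = [
        _fit(grp, cols, ml)
        for ml, grp in marker_table.groupby("motif_length")
        if grp["dnm_count"].sum() > 0
    ]
    return pd.concat(pieces, ignore_index=True)


def step_bias_summary(
    phased_calls: pd.DataFrame,
    rrt_bins: tuple[int, ...] = (0, 20, 40, 60, 80, 141),
) -> dict:
    """Sex-stratified step-size summaries.

    Per parent and motif length: call count, mean |step| in motifs and bp,
    with a two-sided Mann-Whitney rank-sum test of |step in motifs|
    between parents.  Per parent and RRT-length bin: mean signed step and
    expansion fraction (step > 0), capturing the expansion bias at short
    tracts and contraction bias at long ones.
    """
    ph = phased_calls[phased_calls["phase"].isin(["paternal", "maternal"])].copy()
    rows = []
    for ml, grp in ph.groupby("motif_length"):
        rec: dict = {"motif_length": ml}
        samples = {}
        for parent, sub in grp.groupby("phase"):
            rec[f"n_{parent}"] = len(sub)
            rec[f"mean_abs_motifs_{parent}"] = float(sub["step_motifs"].abs().mean())
            rec[f"mean_abs_bp_{parent}"] = float(sub["step_bp"].abs().mean())
            samples[parent] = sub["step_motifs"].abs().to_numpy()
        if len(samples) == 2 and all(len(v) > 0 for v in samples.values()):
            stat, p = scipy.stats.mannwhitneyu(
                samples["maternal"], samples["paternal"], alternative="two-sided"
            )
            rec["mannwhitney_p"] = float(p)
        rows.append(rec)
    per_motif = pd.DataFrame(rows)

    ph["rrt_bin"] = pd.cut(ph["rrt_length"], bins=list(rrt_bins), right=False)
    by_bin = (
        ph.groupby(["phase", "rrt_bin"], observed=True)
        .agg(
            n=("step_motifs", "size"),
            mean_step_motifs=("step_motifs", "mean"),
            expansion_fraction=("step_bp", lambda s: float((s > 0).mean())),
        )
        .reset_index()
    )
    return {"per_motif_length": per_motif, "per_rrt_bin": by_bin}
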