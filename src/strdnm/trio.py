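"""Trio-based microsatellite de novo mutation (mDNM) calling.

An mDNM is called at a marker when the offspring's allele pair cannot be
explained by transmission of one allele from each parent.  With proband
alleles (A1, A2) and parental allele pairs M (mother) and F (father), the
genotype is Mendelian-consistent iff

    (A1 in M and A2 in F)  or  (A1 in F and A2 in M),

where membership means an exact repeat-tract-length match.  A call is made
iff neither statement holds.  Calling is preceded by a strict genotype
quality filter (all three members GQ > threshold) and followed by an
autozygosity proximity filter and parental read-support (allelic dropout)
flagging.  The filter order is fixed: eligibility -> detection ->
autozygosity -> support flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_GQ_THRESHOLD = 60
AUTOZYGOSITY_MAX_DISTANCE = 1_000_000


@dataclass
class TrioGenotypeRecord:
    """Child/mother/father genotypes at one marker (alleles in bp)."""

    marker_id: str
    child_id: str
    child: tuple[int, int]
    mother: tuple[int, int] | None
    father: tuple[int, int] | None
    gq_child: float = np.inf
    gq_mother: float = np.inf
    gq_father: float = np.inf
    mother_support: dict[int, int] | None = None
    father_support: dict[int, int] | None = None

    def __post_init__(self) -> None:
        self.child = tuple(sorted(self.child))
        if self.mother is not None:
            self.mother = tuple(sorted(self.mother))
        if self.father is not None:
            self.father = tuple(sorted(self.father))


def eligible_trio(record: TrioGenotypeRecord, gq_threshold: float = DEFAULT_GQ_THRESHOLD) -> bool:
    """True iff all three members are genotyped with GQ strictly above threshold."""
    if record.mother is None or record.father is None or record.child is None:
        return False
    return (
        record.gq_child > gq_threshold
        and record.gq_mother > gq_threshold
        and record.gq_father > gq_threshold
    )


def is_mendelian_consistent(
    child: tuple[int, int], mother: tuple[int, int], father: tuple[int, int]
) -> bool:
    a1, a2 = child
    in_m = (a1 in mother, a2 in mother)
    in_f = (a1 in father, a2 in father)
    return (in_m[0] and in_f[1]) or (in_f[0] and in_m[1])


def _min_dist(allele: int, pool) -> int:
    return min(abs(allele - p) for p in pool)


def assign_de_novo_allele(
    child: tuple[int, int], mother: tuple[int, int], father: tuple[int, int]
) -> dict:
    """Identify the de novo allele, its progenitor and the step size.

    The de novo allele is the child allele absent from the union of
    parental alleles when exactly one such allele exists.  If both child
    alleles are absent, the one with the larger minimal distance to the
    parental alleles is taken as de novo and the call flagged ambiguous.
    If neither is absent (both child alleles present in a single parent
    only), the allele farther from the uncontributing parent's pair is
    taken as de novo, also flagged ambiguous.  The progenitor is the
    parental allele nearest the de novo allele; on a distance tie the
    smaller parental allele is chosen and the tie flagged.
    """
    union = set(mother) | set(father)
    absent = sorted({a for a in child if a not in union})
    ambiguous = False
    if len(absent) == 1:
        de_novo = absent[0]
        pool = sorted(union)
    elif len(absent) == 2:
        ambiguous = True
        de_novo = max(absent, key=lambda a: (_min_dist(a, union), -a))
        pool = sorted(union)
    else:
        # Inconsistent yet both alleles seen in a parent: one parent carries
        # neither child allele, so the de novo arose on that parent's side.
        ambiguous = True
        missing = father if not any(a in father for a in child) else mother
        de_novo = max(child, key=lambda a: (_min_dist(a, missing), -a))
        pool = sorted(set(missing))
    dist = [abs(de_novo - p) for p in pool]
    best = min(dist)
    candidates = [p for p, d in zip(pool, dist) if d == best]
    progenitor = min(candidates)
    return {
        "de_novo_allele": de_novo,
        "progenitor_allele": progenitor,
        "step_bp": de_novo - progenitor,
        "ambiguous": ambiguous,
        "progenitor_tie": len(candidates) > 1,
    }


def detect_mdnm(record: TrioGenotypeRecord) -> dict | None:
    """Return the de novo call at this marker, or None if consistent."""
    if is_mendelian_consistent(record.child, record.mother, record.father):
        return None
    call = assign_de_novo_allele(record.child, record.mother, record.father)
    call.update(
        marker_id=record.marker_id,
        child_id=record.child_id,
        child_a1=record.child[0],
        child_a2=record.child[1],
        mother_a1=record.mother[0],
        mother_a2=record.mother[1],
        father_a1=record.father[0],
        father_a2=record.father[1],
    )
    return call


def parental_support_category(
    de_novo_allele: int,
    mother_support: dict[int, int] | None,
    father_support: dict[int, int] | None,
    max_reads: int = 2,
    max_fraction: float = 0.05,
) -> str:
    """Classify parental read support for the de novo allele.

    "none": no parental read shows the de novo allele.  "low": in each
    parent fewer than ``max_fraction`` of reads and at most ``max_reads``
    reads show it.  "high" otherwise — a high-support call is a candidate
    parental allelic dropout artefact (the allele was present but missed
    by the parent's genotype).
    """
    if mother_support is None or father_support is None:
        return "unknown"
    counts, fracs = [], []
    for support in (mother_support, father_support):
        total = sum(support.values())
        c = support.get(de_novo_allele, 0)
        counts.append(c)
        fracs.append(c / total if total > 0 else 0.0)
    if sum(counts) == 0:
        return "none"
    if all(c <= max_reads for c in counts) and all(f < max_fraction for f in fracs):
        return "low"
    return "high"


# ---------------------------------------------------------------------------
# Vectorized cohort pipeline
# ---------------------------------------------------------------------------

def build_trio_table(genotypes: pd.DataFrame, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Join per-individual genotypes into one row per (marker, trio).

    ``genotypes`` columns: marker_id, individual_id, allele1, allele2, gq,
    and optionally read_support (mapping or serialized string).
    ``pedigree`` columns: individual_id, father_id, mother_id (trio rows are
    those with both parent ids present).
    """
    trios = pedigree.dropna(subset=["father_id", "mother_id"])
    trios = trios[(trios["father_id"] != "0") & (trios["mother_id"] != "0")]
    cols = ["marker_id", "individual_id", "allele1", "allele2", "gq"]
    has_support = "read_support" in genotypes.columns
    gcols = cols + (["read_support"] if has_support else [])
    g = genotypes[gcols]

    t = g.merge(
        trios[["individual_id", "father_id", "mother_id"]], on="individual_id"
    ).rename(
        columns={
            "individual_id": "child_id",
            "allele1": "c_a1",
            "allele2": "c_a2",
            "gq": "gq_child",
        }
    )
    if has_support:
        t = t.drop(columns=["read_support"])
    for role, key in (("m", "mother_id"), ("f", "father_id")):
        t = t.merge(
            g.rename(
                columns={
                    "individual_id": key,
                    "allele1": f"{role}_a1",
                    "allele2": f"{role}_a2",
                    "gq": f"gq_{'mother' if role == 'm' else 'father'}",
                    "read_support": f"{role}_support",
                }
            ),
            on=["marker_id", key],
            how="left",
        )
    return t


def apply_gq_filter(
    trio_table: pd.DataFrame, gq_threshold: float = DEFAULT_GQ_THRESHOLD
) -> pd.Series:
    """Boolean eligibility per (marker, trio) row: all three GQ strictly above."""
    gq = trio_table[["gq_child", "gq_mother", "gq_father"]]
    complete = trio_table[["m_a1", "f_a1"]].notna().all(axis=1)
    return complete & (gq > gq_threshold).all(axis=1)


def detect_mdnms_table(trio_table: pd.DataFrame) -> pd.Series:
    """Vectorized Mendelian-inconsistency test over eligible rows."""
    c1, c2 = trio_table["c_a1"], trio_table["c_a2"]
    m1, m2 = trio_table["m_a1"], trio_table["m_a2"]
    f1, f2 = trio_table["f_a1"], trio_table["f_a2"]
    c1_in_m = (c1 == m1) | (c1 == m2)
    c2_in_m = (c2 == m1) | (c2 == m2)
    c1_in_f = (c1 == f1) | (c1 == f2)
    c2_in_f = (c2 == f1) | (c2 == f2)
    return ~((c1_in_m & c2_in_f) | (c1_in_f & c2_in_m))


def autozygosity_filter(
    calls: pd.DataFrame, max_distance: int = AUTOZYGOSITY_MAX_DISTANCE
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove pairs of nearby homozygous calls implying a haploid region.

    A call is homozygous when both child alleles equal the de novo allele.
    Any pair of homozygous calls in the same child on the same chromosome
    with start coordinates closer than ``max_distance`` is removed (both
    members), since autozygosity — not mutation — is the likely cause.
    Returns (kept, removed).
    """
    if calls.empty or "chrom" not in calls.columns:
        return calls, calls.iloc[0:0]
    hom = (calls["child_a1"] == calls["child_a2"]) & (
        calls["child_a1"] == calls["de_novo_allele"]
    )
    drop = pd.Series(False, index=calls.index)
    sub = calls[hom].sort_values(["child_id", "chrom", "start"])
    for _, grp in sub.groupby(["child_id", "chrom"], sort=False):
        starts = grp["start"].to_numpy()
        close = np.diff(starts) < max_distance
        flag = np.zeros(len(starts), dtype=bool)
        flag[:-1] |= close
        flag[1:] |= close
        drop.loc[grp.index[flag]] = True
    return calls[~drop], calls[drop]


def per_trio_counts(
    calls: pd.DataFrame, eligibility: pd.DataFrame
) -> pd.DataFrame:
    """Per-trio total call count y_T and available-marker count m_t.

    ``eligibility`` has one row per trio per motif length with column
    ``n_eligible``; trios with m_t = 0 are excluded (they carry no
    information for rate or age models) and reported via a warning.
    """
    m_t = eligibility.groupby("child_id")["n_eligible"].sum().rename("m_t")
    y_t = (
        calls.groupby("child_id").size().rename("y_T")
        if not calls.empty
        else pd.Series(dtype=int, name="y_T")
    )
    out = pd.concat([m_t, y_t], axis=1).fillna({"y_T": 0})
    out["y_T"] = out["y_T"].astype(int)
    zero = out["m_t"] == 0
    if zero.any():
        import warnings

        warnings.warn(f"{int(zero.sum())} trios with no eligible markers excluded")
    return out[~zero].reset_index()


def call_mdnms(
    genotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    catalog: pd.DataFrame,
    gq_threshold: float = DEFAULT_GQ_THRESHOLD,
    blacklist: set[str] | None = None,
    max_autozygosity_distance: int = AUTOZYGOSITY_MAX_DISTANCE,
) -> dict:
    """Full calling pipeline: eligibility -> detection -> autozygosity -> flags.

    ``catalog`` columns: marker_id, chrom, start, end, motif (motif_length
    derived).  Returns a dict with keys ``calls`` (one row per surviving
    MdnmCall), ``eligibility`` (per trio per motif length), ``removed``
    (autozygosity-filtered calls) and ``trio_counts``.
    """
    cat = catalog.copy()
    if "motif_length" not in cat.columns:
        cat["motif_length"] = cat["motif"].str.len()
    if blacklist:
        cat = cat[~cat["marker_id"].isin(blacklist)]
    table = build_trio_table(genotypes, pedigree)
    table = table[table["marker_id"].isin(set(cat["marker_id"]))]
    table = table.sort_values(["child_id", "marker_id"], kind="mergesort").reset_index(
        drop=True
    )

    eligible = apply_gq_filter(table, gq_threshold)
    table = table[eligible].reset_index(drop=True)
    table = table.merge(
        cat[["marker_id", "chrom", "start", "motif", "motif_length"]], on="marker_id"
    )
    eligibility = (
        table.groupby(["child_id", "motif_length"])
        .size()
        .rename("n_eligible")
        .reset_index()
    )

    hit = detect_mdnms_table(table)
    raw = table[hit]
    rows = []
    for rec in raw.itertuples(index=False):
        child = (int(rec.c_a1), int(rec.c_a2))
        mother = (int(rec.m_a1), int(rec.m_a2))
        father = (int(rec.f_a1), int(rec.f_a2))
        call = assign_de_novo_allele(child, mother, father)
        call.update(
            marker_id=rec.marker_id,
            child_id=rec.child_id,
            chrom=rec.chrom,
            start=int(rec.start),
            motif=rec.motif,
            motif_length=int(rec.motif_length),
            child_a1=child[0],
            child_a2=child[1],
            mother_a1=mother[0],
            mother_a2=mother[1],
            father_a1=father[0],
            father_a2=father[1],
        )
        call["step_motifs"] = call["step_bp"] / rec.motif_length
        from .io import parse_support

        call["parental_support"] = parental_support_category(
            call["de_novo_allele"],
            parse_support(getattr(rec, "m_support", None)),
            parse_support(getattr(rec, "f_support", None)),
        )
        rows.append(call)
    calls = pd.DataFrame(rows)
    if not calls.empty:
        calls = calls.sort_values(["child_id", "chrom", "start"]).reset_index(drop=True)
        calls.insert(0, "call_id", calls["marker_id"] + "|" + calls["child_id"])
    kept, removed = autozygosity_filter(calls, max_autozygosity_distance)
    counts = per_trio_counts(kept, eligibility)

    marker_tests = (
        table.groupby("marker_id").size().rename("tested_trios").reset_index()
    )
    if kept.empty:
        marker_tests["dnm_count"] = 0
    else:
        dnm_per_marker = kept.groupby("marker_id").size().rename("dnm_count").reset_index()
        marker_tests = marker_tests.merge(dnm_per_marker, on="marker_id", how="left")
        marker_tests["dnm_count"] = marker_tests["dnm_count"].fillna(0).astype(int)
    attr_cols = [
        c
        for c in ("marker_id", "motif_length", "rrt_length", "gc_content", "purity")
        if c in cat.columns
    ]
    marker_tests = marker_tests.merge(cat[attr_cols], on="marker_id", how="left")

    return {
        "calls": kept.reset_index(drop=True),
        "removed": removed.reset_index(drop=True),
        "eligibility": eligibility,
        "trio_counts": counts,
        "marker_tests": marker_tests,
    }
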