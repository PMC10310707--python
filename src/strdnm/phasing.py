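"""Parent-of-origin phasing of mDNM calls.

Three independent sources of evidence are used, mirroring how trio studies
phase de novo events:

* **read tracing** — sequencing reads that report the de novo allele and are
  assigned to a parental haplotype by flanking phased variants;
* **allele sharing** — when the de novo allele is seen in neither parent and
  the child's other allele is seen in only one parent, the de novo came
  from the *other* parent;
* **three-generation haplotype sharing** — when the proband has children, a
  transmitted de novo is phased to the parent whose haplotype the
  grandchild inherited at the locus, and a non-transmitted de novo to the
  opposite parent.

Conflicting evidence (within or between methods) yields ``unknown`` rather
than a majority vote; the latent-phase age model downstream handles
unphased events natively, so unknown is the conservative output.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

PATERNAL = "paternal"
MATERNAL = "maternal"
UNKNOWN = "unknown"
METHODS = ("read", "allele", "threegen")


def phase_by_reads(evidence: pd.DataFrame) -> str:
    """Phase one call from haplotype-labelled reads.

    ``evidence`` rows carry ``parental_haplotype`` and ``supports_de_novo``.
    The call is phased to the haplotype of the supporting reads when all of
    them agree; no supporting phased reads, or conflicting labels, give
    ``unknown``.
    """
    if evidence is None or evidence.empty:
        return UNKNOWN
    sup = evidence[evidence["supports_de_novo"].astype(bool)]
    labels = set(sup["parental_haplotype"])
    if len(labels) == 1:
        return labels.pop()
    return UNKNOWN


def phase_by_allele_sharing(
    de_novo_allele: int,
    other_allele: int,
    mother: tuple[int, int],
    father: tuple[int, int],
) -> str:
    """Phase by exclusion of the non-de-novo child allele.

    Applicable only when the de novo allele is absent from both parents;
    if the other child allele is carried by exactly one parent, it must
    have been transmitted by that parent, so the de novo allele came from
    the other one.
    """
    if de_novo_allele in mother or de_novo_allele in father:
        return UNKNOWN
    in_m = other_allele in mother
    in_f = other_allele in father
    if in_m and not in_f:
        return PATERNAL
    if in_f and not in_m:
        return MATERNAL
    return UNKNOWN


def phase_by_three_gen(evidence: pd.DataFrame) -> str:
    """Phase from transmission to grandchildren.

    Each row records whether a grandchild inherited the de novo allele
    (``transmitted``) and which grandparental haplotype the proband passed
    on at the locus (``proband_haplotype_origin``).  A transmitted de novo
    sits on the haplotype the grandchild received; a non-transmitted one
    sits on the opposite haplotype.  Grandchildren implying different
    parents give ``unknown``.
    """
    if evidence is None or evidence.empty:
        return UNKNOWN
    implied = set()
    for row in evidence.itertuples(index=False):
        origin = row.proband_haplotype_origin
        if origin not in (PATERNAL, MATERNAL):
            continue
        if bool(row.transmitted):
            implied.add(origin)
        else:
            implied.add(PATERNAL if origin == MATERNAL else MATERNAL)
    if len(implied) == 1:
        return implied.pop()
    return UNKNOWN


def consolidate_phases(method_calls: dict[str, str]) -> str:
    """Consensus parent across methods: unique non-unknown label, else unknown."""
    labels = {p for p in method_calls.values() if p != UNKNOWN}
    if len(labels) == 1:
        return labels.pop()
    return UNKNOWN


def concordance_matrix(phased: pd.DataFrame) -> pd.DataFrame:
    """Pairwise agreement among calls phased by both methods of each pair."""
    rows = []
    for a, b in itertools.combinations(METHODS, 2):
        both = phased[(phased[f"phase_{a}"] != UNKNOWN) & (phased[f"phase_{b}"] != UNKNOWN)]
        n = len(both)
        agree = int((both[f"phase_{a}"] == both[f"phase_{b}"]).sum())
        rows.append(
            {
                "method_a": a,
                "method_b": b,
                "n_both_phased": n,
                "n_agree": agree,
                "concordance": agree / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def phase_calls(
    calls: pd.DataFrame,
    read_evidence: pd.DataFrame | None = None,
    threegen_evidence: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply all three phasing methods to a call table and consolidate.

    ``calls`` must carry call_id, de_novo_allele, child/mother/father
    alleles.  Evidence tables are keyed by call_id.  Returns the call table
    with per-method columns ``phase_read``, ``phase_allele``,
    ``phase_threegen`` and a ``phase`` consensus column, plus the pairwise
    concordance matrix.
    """
    out = calls.copy()
    read_groups = (
        dict(tuple(read_evidence.groupby("call_id")))
        if read_evidence is not None and not read_evidence.empty
        else {}
    )
    tg_groups = (
        dict(tuple(threegen_evidence.groupby("call_id")))
        if threegen_evidence is not None and not threegen_evidence.empty
        else {}
    )
    per_method: dict[str, list[str]] = {m: [] for m in METHODS}
    consensus = []
    for row in out.itertuples(index=False):
        dn = row.de_novo_allele
        other = row.child_a1 if row.child_a2 == dn else row.child_a2
        methods = {
            "read": phase_by_reads(read_groups.get(row.call_id)),
            "allele": phase_by_allele_sharing(
                dn,
                other,
                (row.mother_a1, row.mother_a2),
                (row.father_a1, row.father_a2),
            ),
            "threegen": phase_by_three_gen(tg_groups.get(row.call_id)),
        }
        for m in METHODS:
            per_method[m].append(methods[m])
        consensus.append(consolidate_phases(methods))
    for m in METHODS:
        out[f"phase_{m}"] = per_method[m]
    out["phase"] = consensus
    return out, concordance_matrix(out)


def phased_trio_counts(phased: pd.DataFrame, trios: pd.DataFrame) -> pd.DataFrame:
    """Per-trio (y_P, y_M, y_U) with ages and availability: age-model input.

    ``trios`` carries child_id, father_age, mother_age and m_t; trios with
    no calls contribute zero counts.
    """
    if phased.empty:
        counts = pd.DataFrame(columns=["paternal", "maternal", "unknown"])
    else:
        counts = phased.groupby(["child_id", "phase"]).size().unstack(fill_value=0)
    for col in ("paternal", "maternal", "unknown"):
        if col not in counts.columns:
            counts[col] = 0
    counts = counts.reindex(trios["child_id"]).fillna(0).astype(int)
    return pd.DataFrame(
        {
            "child_id": trios["child_id"].to_numpy(),
            "y_p": counts["paternal"].to_numpy(),
            "y_m": counts["maternal"].to_numpy(),
            "y_u": counts["unknown"].to_numpy(),
            "father_age": trios["father_age"].to_numpy(),
            "mother_age": trios["mother_age"].to_numpy(),
            "m_t": trios["m_t"].to_numpy(),
        }
    )
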