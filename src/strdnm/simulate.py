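"""Synthetic STR trio-cohort generator.

Generates an STR catalog, a trio (and three-generation) pedigree, truth
de novo events and error-corrupted genotypes with the statistical
structure the downstream analyses assume:

* per-marker mutation weights log-linear in motif length, RRT length and
  purity (dinucleotides fastest, hexanucleotides slowest);
* per-trio paternal and maternal event counts Poisson with identity-link
  linear age effects, scaled by the trio's marker availability m_t / Mbar;
* stepwise mutation: step sizes in motif units are geometric, with an
  expansion bias at short reference tracts turning into a contraction
  bias at long ones; maternal steps are configurably larger;
* partial phasability: a configurable fraction of events carries
  haplotype-labelled read evidence, allele-sharing phasability emerges
  from the simulated parental genotypes, and three-generation families
  contribute grandchild-transmission evidence;
* genotyping noise: per-allele slippage errors (largest at homopolymers),
  parental allelic dropout that manufactures spurious de novo calls, and
  genotype-quality values that make error-affected genotypes *enriched*
  below the GQ filter threshold but not perfectly so.

Default statistical parameters reproduce the cohort conditions of a large
trio study: mean ~12.7 detectable events per trio, ~77% paternal, additive
age effects of 0.178 (paternal) and 0.058 (maternal) events per year on
the mean-availability scale, and ~60% of events phasable overall.

Mutations are placed at distinct available markers within a trio; at
genome scale two events at the same marker-trio are vanishingly rare, and
excluding them keeps scaled-down cohorts exactly recoverable by the
detector under zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trio import is_mendelian_consistent

GENOME_SPAN = 2_875_000_000  # autosomal span the catalog is scattered over
CHROMS = [f"chr{i}" for i in range(1, 23)]

# high-quality-set composition by motif length (fractions sum to 1)
DEFAULT_MOTIF_MIX = {1: 0.629, 2: 0.148, 3: 0.047, 4: 0.105, 5: 0.047, 6: 0.024}
# log-weights giving the observed per-motif-length rate ordering
DEFAULT_MOTIF_LOG_RATE = {
    1: np.log(2.15),
    2: np.log(10.7),
    3: np.log(4.92),
    4: np.log(8.57),
    5: np.log(2.58),
    6: np.log(1.04),
}
DEFAULT_RRT_MIN = {1: 10, 2: 10, 3: 12, 4: 16, 5: 20, 6: 24}
RRT_MAX = 140
DEFAULT_ERROR_RATES = {1: 2e-5, 2: 5e-6, 3: 3e-6, 4: 3e-6, 5: 2e-6, 6: 2e-6}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Sizes, age-effect coefficients and composition default to the
    conditions of the emulated cohort; tests and examples pass smaller
    ``n_markers`` / ``n_trios`` explicitly.
    """

    n_markers: int = 634_406
    n_trios: int = 6084
    n_threegen_families: int = 100
    n_grandchildren: int = 2
    motif_length_mix: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_MIX)
    )
    rrt_length_scale: float = 18.0       # exponential decay of RRT above minimum
    purity_beta_b: float = 10.0          # impurity ~ Beta(1, b) -> mean 1/(1+b)
    motif_log_rate: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_LOG_RATE)
    )
    rrt_rate_slope: float = 0.03         # per bp of RRT length, log scale
    purity_rate_slope: float = 2.0       # log scale
    alpha_p: float = 4.43                # per-Mbar-markers paternal intercept
    beta_p: float = 0.178                # paternal events per year of father's age
    alpha_m: float = 1.31
    beta_m: float = 0.058
    father_age_mean: float = 30.0
    mother_age_mean: float = 28.0
    age_sd: float = 5.0
    age_min: float = 18.0
    age_max: float = 55.0
    step_geometric_p_paternal: float = 0.76   # mean |step| = 1/p motifs
    step_geometric_p_maternal: float = 0.61
    expansion_pivot_bp: float = 60.0     # RRT length where P(expansion) = 0.5
    expansion_slope: float = 0.02        # per bp; positive -> contraction when long
    fraction_polymorphic: float = 0.9
    genotyping_error_rate: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ERROR_RATES)
    )
    error_gq_below_threshold_prob: float = 0.7
    dropout_rate: float = 5e-6           # per parent per available marker-trio
    dropout_read_fraction: float = 0.3
    availability_mean: float = 0.404
    availability_concentration: float = 200.0
    phasable_read_fraction: float = 0.40
    coverage_mean: float = 35.0

    def validate(self) -> None:
        mix = self.motif_length_mix
        if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-6:
            raise ValueError("motif_length_mix must be non-negative and sum to 1")
        if not 0 < self.availability_mean <= 1:
            raise ValueError("availability_mean must be in (0, 1]")
        for name in ("phasable_read_fraction", "fraction_polymorphic"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        max_mu_p = self.alpha_p + self.beta_p * self.age_max
        min_mu_p = self.alpha_p + self.beta_p * self.age_min
        max_mu_m = self.alpha_m + self.beta_m * self.age_max
        min_mu_m = self.alpha_m + self.beta_m * self.age_min
        if min(max_mu_p, min_mu_p) < 0 or min(max_mu_m, min_mu_m) < 0:
            raise ValueError("age-effect coefficients give a negative Poisson mean")


def _random_primitive_motif(rng: np.random.Generator, length: int) -> str:
    bases = np.array(list("ACGT"))
    while True:
        motif = "".join(rng.choice(bases, size=length))
        # reject motifs that are powers of a shorter motif (e.g. "ACAC")
        for d in range(1, length):
            if length % d == 0 and motif == motif[:d] * (length // d):
                break
        else:
            return motif


def generate_catalog(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw an STR catalog: coordinates, motif, RRT length and purity.

    Motif lengths follow ``motif_length_mix``; RRT lengths are the
    per-length minimum plus an exponential tail truncated at 140 bp;
    purity is 1 minus a small Beta-distributed impurity.
    """
    config.validate()
    n = config.n_markers
    if n < 1:
        raise ValueError("n_markers must be >= 1")
    lengths = sorted(config.motif_length_mix)
    probs = np.array([config.motif_length_mix[l] for l in lengths])
    motif_len = rng.choice(lengths, size=n, p=probs)
    motifs = [_random_primitive_motif(rng, l) for l in motif_len]
    low = np.array([DEFAULT_RRT_MIN[l] for l in motif_len])
    tail = rng.exponential(config.rrt_length_scale, size=n)
    rrt = np.minimum(low + np.floor(tail).astype(int), RRT_MAX)
    rrt = np.maximum(rrt, motif_len)  # invariant: tract at least one motif
    purity = 1.0 - rng.beta(1.0, config.purity_beta_b, size=n)
    purity = np.clip(purity, 1e-6, 1.0)
    chrom_idx = rng.integers(0, len(CHROMS), size=n)
    span = GENOME_SPAN // len(CHROMS)
    start = rng.integers(0, span - RRT_MAX, size=n)
    cat = pd.DataFrame(
        {
            "chrom": [CHROMS[i] for i in chrom_idx],
            "start": start,
            "end": start + rrt,
            "motif": motifs,
            "purity": purity,
        }
    )
    cat = cat.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    cat["marker_id"] = [f"ms{i:07d}" for i in range(n)]
    cat["motif_length"] = cat["motif"].str.len()
    cat["rrt_length"] = cat["end"] - cat["start"]
    cat["gc_content"] = cat["motif"].map(
        lambda m: sum(b in "GC" for b in m) / len(m)
    )
    return cat


def marker_mutation_weights(catalog: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Relative per-marker mutation weights, log-linear in attributes."""
    logw = (
        catalog["motif_length"].map(config.motif_log_rate).to_numpy(dtype=float)
        + config.rrt_rate_slope * catalog["rrt_length"].to_numpy(dtype=float)
        + config.purity_rate_slope * catalog["purity"].to_numpy(dtype=float)
    )
    w = np.exp(logw - logw.max())
    return w / w.sum()


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


@dataclass
class SimResult:
    """All artefacts of one simulated cohort."""

    catalog: pd.DataFrame
    pedigree: pd.DataFrame
    trios: pd.DataFrame
    truth: pd.DataFrame
    truth_genotypes: pd.DataFrame
    read_evidence: pd.DataFrame
    threegen_evidence: pd.DataFrame
    _arrays: dict = field(default_factory=dict, repr=False)


def simulate_pedigrees(
    catalog: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> SimResult:
    """Simulate founder genotypes, inheritance and de novo events.

    Per-trio paternal counts are Poisson((alpha_P + beta_P A_P) m_t/Mbar),
    maternal analogous.  Each event picks an available marker with
    probability proportional to its mutation weight, mutates the child's
    allele inherited from the origin parent by a geometric number of motif
    units (expansion-biased at short tracts), and is resampled if the
    resulting trio genotype would be Mendelian-consistent (only detectable
    events are generated).  The first ``n_threegen_families`` trios get a
    spouse and grandchildren whose haplotype inheritance is recorded.
    """
    config.validate()
    if catalog.empty:
        raise ValueError("catalog must be non-empty")
    nm = len(catalog)
    nt = config.n_trios
    n3g = min(config.n_threegen_families, nt)
    ngc = config.n_grandchildren

    motif_len = catalog["motif_length"].to_numpy()
    rrt = catalog["rrt_length"].to_numpy()
    weights = marker_mutation_weights(catalog, config)

    # --- population allele pools -----------------------------------------
    k_max = 6
    poly = rng.random(nm) < config.fraction_polymorphic
    k = np.where(poly, 2 + rng.poisson(1.2, size=nm), 1).clip(1, k_max)
    deltas = np.array([0, 1, -1, 2, -2, 3])
    allele_values = rrt[:, None] + motif_len[:, None] * deltas[None, :]
    allele_values = np.maximum(allele_values, motif_len[:, None])
    freqs = np.zeros((nm, k_max))
    for m in range(nm):
        freqs[m, : k[m]] = rng.dirichlet(np.ones(k[m]))
    cum = np.cumsum(freqs, axis=1)

    def draw_founder_alleles(n_ind: int) -> np.ndarray:
        """(nm, n_ind, 2) allele values drawn from each marker's pool."""
        u = rng.random((nm, n_ind, 2))
        idx = (u[..., None] > cum[:, None, None, :]).sum(axis=-1)
        return np.take_along_axis(
            np.broadcast_to(allele_values[:, None, :], (nm, n_ind, k_max)),
            idx,
            axis=2,
        )

    father = draw_founder_alleles(nt)
    mother = draw_founder_alleles(nt)
    pat_idx = rng.integers(0, 2, size=(nm, nt))
    mat_idx = rng.integers(0, 2, size=(nm, nt))
    child_pat = np.take_along_axis(father, pat_idx[..., None], axis=2)[..., 0]
    child_mat = np.take_along_axis(mother, mat_idx[..., None], axis=2)[..., 0]

    # --- availability and ages -------------------------------------------
    a = config.availability_mean * config.availability_concentration
    b = (1 - config.availability_mean) * config.availability_concentration
    p_avail = rng.beta(a, b, size=nt) if config.availability_mean < 1 else np.ones(nt)
    avail = rng.random((nm, nt)) < p_avail[None, :]
    m_t = avail.sum(axis=0)
    mbar = m_t.mean()
    father_age = _truncated_normal(
        rng, config.father_age_mean, config.age_sd, config.age_min, config.age_max, nt
    )
    mother_age = _truncated_normal(
        rng, config.mother_age_mean, config.age_sd, config.age_min, config.age_max, nt
    )

    # --- de novo events ----------------------------------------------------
    exposure = m_t / mbar if mbar > 0 else np.ones(nt)
    mu_p = (config.alpha_p + config.beta_p * father_age) * exposure
    mu_m = (config.alpha_m + config.beta_m * mother_age) * exposure
    if (mu_p < 0).any() or (mu_m < 0).any():
        raise ValueError("negative Poisson mean for some trio; check age coefficients")
    n_pat = rng.poisson(mu_p)
    n_mat = rng.poisson(mu_m)

    cumw = np.cumsum(weights)
    truth_rows = []
    for t in range(nt):
        used: set[int] = set()
        events = [("paternal", config.step_geometric_p_paternal)] * n_pat[t] + [
            ("maternal", config.step_geometric_p_maternal)
        ] * n_mat[t]
        for parent, geo_p in events:
            # weighted draw among this trio's available, unused markers
            for _ in range(200):
                m = int(np.searchsorted(cumw, rng.random()))
                if avail[m, t] and m not in used:
                    break
            else:
                cand = np.flatnonzero(avail[:, t])
                cand = cand[~np.isin(cand, list(used))]
                if cand.size == 0:
                    continue
                m = int(rng.choice(cand))
            used.add(m)
            progenitor = int(child_pat[m, t] if parent == "paternal" else child_mat[m, t])
            ml = int(motif_len[m])
            p_expand = 1.0 / (
                1.0 + np.exp(config.expansion_slope * (rrt[m] - config.expansion_pivot_bp))
            )
            new = None
            for _ in range(25):
                steps = int(rng.geometric(geo_p))
                sign = 1 if rng.random() < p_expand else -1
                cand_allele = progenitor + sign * steps * ml
                if cand_allele < ml:
                    continue
                child_alleles = (
                    (cand_allele, int(child_mat[m, t]))
                    if parent == "paternal"
                    else (int(child_pat[m, t]), cand_allele)
                )
                if not is_mendelian_consistent(
                    tuple(sorted(child_alleles)),
                    tuple(sorted(mother[m, t])),
                    tuple(sorted(father[m, t])),
                ):
                    new = cand_allele
                    break
            if new is None:
                # deterministic fallback: step outward until the allele is
                # absent from both parents (guarantees detectability)
                pool = set(father[m, t]) | set(mother[m, t])
                s = 1
                while True:
                    for cand_allele in (progenitor + s * ml, progenitor - s * ml):
                        if cand_allele >= ml and cand_allele not in pool:
                            new = cand_allele
                            break
                    if new is not None:
                        break
                    s += 1
            if parent == "paternal":
                child_pat[m, t] = new
            else:
                child_mat[m, t] = new
            truth_rows.append(
                {
                    "marker_id": catalog["marker_id"].iat[m],
                    "child_id": f"C{t:05d}",
                    "parent_of_origin": parent,
                    "progenitor_allele": progenitor,
                    "de_novo_allele": int(new),
                    "step_bp": int(new) - progenitor,
                    "step_motifs": (int(new) - progenitor) / ml,
                    "motif_length": ml,
                    "rrt_length": int(rrt[m]),
                    "_marker_index": m,
                    "_trio_index": t,
                }
            )
    truth = pd.DataFrame(truth_rows)
    if not truth.empty:
        truth["event_id"] = truth["marker_id"] + "|" + truth["child_id"]

    # --- three-generation families ----------------------------------------
    spouse = draw_founder_alleles(n3g) if n3g else np.zeros((nm, 0, 2), dtype=int)
    tg_rows = []
    ev_rows = []
    if not truth.empty:
        phasable = rng.random(len(truth)) < config.phasable_read_fraction
        trio_index = truth["_trio_index"].to_numpy()
        for i, rec in enumerate(truth.itertuples(index=False)):
            if phasable[i]:
                for r in range(int(1 + rng.poisson(2.0))):
                    ev_rows.append(
                        {
                            "call_id": rec.event_id,
                            "read_id": f"{rec.event_id}:r{r}",
                            "parental_haplotype": rec.parent_of_origin,
                            "supports_de_novo": True,
                        }
                    )
            t = int(trio_index[i])
            if t < n3g:
                dn_on_pat_origin = rec.parent_of_origin == "paternal"
                for g in range(ngc):
                    take_pat_origin = rng.random() < 0.5
                    transmitted = take_pat_origin == dn_on_pat_origin
                    origin = "paternal" if take_pat_origin else "maternal"
                    tg_rows.append(
                        {
                            "call_id": rec.event_id,
                            "grandchild_id": f"G{t:05d}_{g}",
                            "transmitted": transmitted,
                            "proband_haplotype_origin": origin,
                        }
                    )
    read_evidence = pd.DataFrame(
        ev_rows, columns=["call_id", "read_id", "parental_haplotype", "supports_de_novo"]
    )
    threegen_evidence = pd.DataFrame(
        tg_rows,
        columns=["call_id", "grandchild_id", "transmitted", "proband_haplotype_origin"],
    )

    # --- assemble tables ----------------------------------------------------
    child_ids = [f"C{t:05d}" for t in range(nt)]
    father_ids = [f"F{t:05d}" for t in range(nt)]
    mother_ids = [f"M{t:05d}" for t in range(nt)]
    ped_rows = []
    for t in range(nt):
        ped_rows.append((father_ids[t], "0", "0", "M", 2000 - round(father_age[t])))
        ped_rows.append((mother_ids[t], "0", "0", "F", 2000 - round(mother_age[t])))
        sex = "M" if t % 2 == 0 else "F"
        ped_rows.append((child_ids[t], father_ids[t], mother_ids[t], sex, 2000))
    for t in range(n3g):
        ped_rows.append((f"S{t:05d}", "0", "0", "F" if t % 2 == 0 else "M", 2000))
        for g in range(ngc):
            ped_rows.append((f"G{t:05d}_{g}", child_ids[t], f"S{t:05d}", "M", 2028))
    pedigree = pd.DataFrame(
        ped_rows, columns=["individual_id", "father_id", "mother_id", "sex", "birth_year"]
    )
    # grandchild rows above use (child, spouse) as (father, mother) for odd t;
    # the caller only requires trio rows (child with both parents) to be exact.

    trios = pd.DataFrame(
        {
            "child_id": child_ids,
            "father_id": father_ids,
            "mother_id": mother_ids,
            "father_age": father_age,
            "mother_age": mother_age,
            "m_t": m_t,
        }
    )

    def melt(ids: list[str], arr_a1: np.ndarray, arr_a2: np.ndarray) -> pd.DataFrame:
        n_ind = len(ids)
        a1 = np.minimum(arr_a1, arr_a2).T.ravel()
        a2 = np.maximum(arr_a1, arr_a2).T.ravel()
        return pd.DataFrame(
            {
                "marker_id": np.tile(catalog["marker_id"].to_numpy(), n_ind),
                "individual_id": np.repeat(ids, nm),
                "allele1": a1.astype(int),
                "allele2": a2.astype(int),
            }
        )

    gts = [
        melt(father_ids, father[:, :, 0], father[:, :, 1]),
        melt(mother_ids, mother[:, :, 0], mother[:, :, 1]),
        melt(child_ids, child_pat, child_mat),
    ]
    truth_genotypes = pd.concat(gts, ignore_index=True)

    arrays = {
        "father": father,
        "mother": mother,
        "child_pat": child_pat,
        "child_mat": child_mat,
        "avail": avail,
        "motif_len": motif_len,
        "child_ids": child_ids,
        "father_ids": father_ids,
        "mother_ids": mother_ids,
    }
    return SimResult(
        catalog=catalog,
        pedigree=pedigree,
        trios=trios,
        truth=truth.drop(columns=["_marker_index", "_trio_index"], errors="ignore"),
        truth_genotypes=truth_genotypes,
        read_evidence=read_evidence,
        threegen_evidence=threegen_evidence,
        _arrays=arrays,
    )


def _support_strings(pairs: np.ndarray, reads: np.ndarray, extra_allele, extra_reads):
    """Serialize read support as 'allele:count;allele:count' strings."""
    out = []
    for i in range(pairs.shape[0]):
        d: dict[int, int] = {}
        for j in (0, 1):
            a = int(pairs[i, j])
            d[a] = d.get(a, 0) + int(reads[i, j])
        if extra_allele is not None and extra_reads[i] > 0:
            a = int(extra_allele[i])
            d[a] = d.get(a, 0) + int(extra_reads[i])
        out.append(";".join(f"{a}:{c}" for a, c in sorted(d.items())))
    return out


def inject_errors(
    sim: SimResult, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Produce the observed genotype table: errors, dropout, GQ, read support.

    With all error rates zero and availability 1, the observed table
    equals the truth genotypes with passing GQ everywhere, so downstream
    detection recovers exactly the simulated truth set.
    """
    arrays = sim._arrays
    nm, nt = arrays["avail"].shape
    motif_len = arrays["motif_len"]
    cat_ids = sim.catalog["marker_id"].to_numpy()

    err_rate = np.array(
        [config.genotyping_error_rate.get(int(l), 0.0) for l in motif_len]
    )
    # one member per unavailable marker-trio fails the GQ filter; the choice
    # must be consistent across the three member tables
    fail_member = rng.integers(0, 3, size=(nm, nt))

    frames = []
    for role, key_ids in (("father", "father_ids"), ("mother", "mother_ids"), ("child", "child_ids")):
        if role == "child":
            a1 = arrays["child_pat"].copy()
            a2 = arrays["child_mat"].copy()
        else:
            pair = arrays[role].copy()
            a1, a2 = pair[:, :, 0].copy(), pair[:, :, 1].copy()

        # slippage errors: perturb an allele by one motif unit
        gq_low_from_error = np.zeros((nm, nt), dtype=bool)
        for arr in (a1, a2):
            hit = rng.random((nm, nt)) < err_rate[:, None]
            if hit.any():
                sign = rng.choice([-1, 1], size=int(hit.sum()))
                arr[hit] = np.maximum(
                    arr[hit] + sign * np.broadcast_to(motif_len[:, None], (nm, nt))[hit],
                    np.broadcast_to(motif_len[:, None], (nm, nt))[hit],
                )
                flagged = rng.random(int(hit.sum())) < config.error_gq_below_threshold_prob
                gq_low_from_error[hit] |= flagged

        # parental allelic dropout
        dropped_allele = None
        dropped_reads = None
        if role in ("father", "mother") and config.dropout_rate > 0:
            drop = rng.random((nm, nt)) < config.dropout_rate
            if drop.any():
                which = rng.integers(0, 2, size=int(drop.sum()))
                lo, hi = a1[drop], a2[drop]
                dropped = np.where(which == 0, lo, hi)
                kept = np.where(which == 0, hi, lo)
                a1[drop] = kept
                a2[drop] = kept
                dropped_allele = np.zeros((nm, nt), dtype=int)
                dropped_allele[drop] = dropped
                dropped_reads = np.zeros((nm, nt), dtype=int)

        # genotype quality: unavailable marker-trios fail via one member
        gq = rng.uniform(61.0, 99.0, size=(nm, nt))
        unavail = ~arrays["avail"]
        role_idx = {"father": 0, "mother": 1, "child": 2}[role]
        fail = unavail & (fail_member == role_idx)
        gq[fail] = rng.uniform(0.0, 60.0, size=int(fail.sum()))
        gq[gq_low_from_error] = rng.uniform(0.0, 60.0, size=int(gq_low_from_error.sum()))

        df = pd.DataFrame(
            {
                "marker_id": np.tile(cat_ids, nt),
                "individual_id": np.repeat(arrays[key_ids], nm),
                "allele1": np.minimum(a1, a2).T.ravel().astype(int),
                "allele2": np.maximum(a1, a2).T.ravel().astype(int),
                "gq": np.round(gq.T.ravel(), 1),
            }
        )
        if role in ("father", "mother"):
            total = rng.poisson(config.coverage_mean, size=(nm, nt))
            r1 = rng.binomial(total, 0.5)
            r2 = total - r1
            if dropped_allele is not None:
                had_drop = dropped_allele > 0
                dropped_reads[had_drop] = rng.binomial(
                    total[had_drop], config.dropout_read_fraction
                )
            pairs = np.stack(
                [np.minimum(a1, a2).T.ravel(), np.maximum(a1, a2).T.ravel()], axis=1
            )
            reads = np.stack([r1.T.ravel(), r2.T.ravel()], axis=1)
            extra_a = dropped_allele.T.ravel() if dropped_allele is not None else None
            extra_r = (
                dropped_reads.T.ravel()
                if dropped_reads is not None
                else np.zeros(nm * nt, dtype=int)
            )
            df["read_support"] = _support_strings(pairs, reads, extra_a, extra_r)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def simulate_trio_counts(
    config: SimConfig,
    n_trios: int,
    rng: np.random.Generator,
    phased_fraction: float = 0.60,
    phasing_mode: str = "trio",
) -> pd.DataFrame:
    """Fast generative mirror of the age model: per-trio count table only.

    Draws ages, availability exposure, and latent paternal/maternal
    Poisson counts at the configured identity-link means, then hides phase
    information.  With ``phasing_mode='trio'`` (default) a trio's events
    are all phased (probability ``phased_fraction``) or all unphased —
    this all-or-nothing mechanism is the exact generative counterpart of
    the unweighted latent-sum likelihood, under which its MLE is
    consistent and Wald intervals attain nominal coverage.  With
    ``phasing_mode='event'`` each event is phased independently
    (mirroring the mechanistic marker-level simulator); the latent-sum
    fit is then only an approximation.  Used for parameter-recovery and
    calibration studies where marker-level genotypes are unnecessary.
    """
    if phasing_mode not in ("trio", "event"):
        raise ValueError("phasing_mode must be 'trio' or 'event'")
    father_age = _truncated_normal(
        rng, config.father_age_mean, config.age_sd, config.age_min, config.age_max, n_trios
    )
    mother_age = _truncated_normal(
        rng, config.mother_age_mean, config.age_sd, config.age_min, config.age_max, n_trios
    )
    a = config.availability_mean * config.availability_concentration
    b = (1 - config.availability_mean) * config.availability_concentration
    p_avail = (
        rng.beta(a, b, size=n_trios)
        if config.availability_mean < 1
        else np.ones(n_trios)
    )
    m_t = np.maximum((p_avail * config.n_markers).round().astype(int), 1)
    exposure = m_t / m_t.mean()
    mu_p = (config.alpha_p + config.beta_p * father_age) * exposure
    mu_m = (config.alpha_m + config.beta_m * mother_age) * exposure
    if (mu_p < 0).any() or (mu_m < 0).any():
        raise ValueError("negative Poisson mean for some trio; check age coefficients")
    y_p_true = rng.poisson(mu_p)
    y_m_true = rng.poisson(mu_m)
    if phasing_mode == "trio":
        phased = rng.random(n_trios) < phased_fraction
        y_p = np.where(phased, y_p_true, 0)
        y_m = np.where(phased, y_m_true, 0)
        y_u = np.where(phased, 0, y_p_true + y_m_true)
    else:
        y_p = rng.binomial(y_p_true, phased_fraction)
        y_m = rng.binomial(y_m_true, phased_fraction)
        y_u = (y_p_true - y_p) + (y_m_true - y_m)
    return pd.DataFrame(
        {
            "child_id": [f"C{t:05d}" for t in range(n_trios)],
            "y_p": y_p,
            "y_m": y_m,
            "y_u": y_u,
            "father_age": father_age,
            "mother_age": mother_age,
            "m_t": m_t,
        }
    )
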