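"""Readers and writers for the catalog, pedigree, genotype and result tables.

Formats are deliberately plain: the STR catalog is a BED-dialect TSV
(chrom, start, end, motif; 0-based half-open, no header), the pedigree a
FAM-like whitespace table, and everything else headered TSV.  All
coordinates are 0-based half-open everywhere; alleles are total repeat
tract lengths in bp.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .catalog import DNA, StrRecord

log = logging.getLogger("strdnm")

PEDIGREE_COLUMNS = ["individual_id", "father_id", "mother_id", "sex", "birth_year"]


class CatalogParseError(ValueError):
    pass


def read_catalog(path: str | Path) -> list[StrRecord]:
    """Parse a BED-dialect STR catalog into records.

    Each line: chrom, start, end, motif (tab-separated, 4+ columns).
    Malformed lines raise :class:`CatalogParseError` naming the line
    number; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[StrRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CatalogParseError(f"line {lineno}: expected 4+ columns, got {len(fields)}")
            chrom, start_s, end_s, motif = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CatalogParseError(f"line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise CatalogParseError(f"line {lineno}: start >= end ({start} >= {end})")
            if not set(motif.upper()) <= DNA:
                raise CatalogParseError(f"line {lineno}: invalid motif {motif!r}")
            try:
                records.append(StrRecord(chrom, start, end, motif))
            except ValueError as exc:
                raise CatalogParseError(f"line {lineno}: {exc}") from exc
    if not records:
        warnings.warn(f"catalog {path} is empty")
    return records


def catalog_to_frame(records: list[StrRecord]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "motif": r.motif,
            "purity": r.purity,
            "marker_id": r.marker_id,
            "motif_length": r.motif_length,
            "rrt_length": r.rrt_length,
            "gc_content": r.gc_content,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    """Write the catalog as BED-dialect TSV (sorted, 0-based half-open)."""
    out = catalog.sort_values(["chrom", "start"], kind="mergesort")
    out[["chrom", "start", "end", "motif"]].to_csv(path, sep="\t", header=False, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a single-header-line TSV."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
    log.info("wrote %s (%d rows)", path, len(df))


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a FAM-like whitespace pedigree (no header).

    Columns: individual_id, father_id, mother_id, sex, birth_year; '0'
    marks a missing parent.  An individual appearing in its own ancestry
    is rejected.
    """
    ped = pd.read_csv(path, sep=r"\s+", header=None, names=PEDIGREE_COLUMNS, dtype=str)
    ped["birth_year"] = pd.to_numeric(ped["birth_year"], errors="coerce")
    both = (ped["father_id"] != "0") & (ped["mother_id"] != "0")
    neither = (ped["father_id"] == "0") & (ped["mother_id"] == "0")
    if not (both | neither).all():
        bad = ped.loc[~(both | neither), "individual_id"].tolist()
        raise ValueError(f"individuals with exactly one parent recorded: {bad}")
    parent_map = {
        r.individual_id: (r.father_id, r.mother_id) for r in ped.itertuples(index=False)
    }
    for ind in parent_map:
        seen = set()
        stack = [ind]
        while stack:
            cur = stack.pop()
            for p in parent_map.get(cur, ("0", "0")):
                if p == "0":
                    continue
                if p == ind:
                    raise ValueError(f"{ind} is its own ancestor")
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
    return ped


def write_pedigree(ped: pd.DataFrame, path: str | Path) -> None:
    ped[PEDIGREE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
        comment="#",
    )


def parse_support(value) -> dict[int, int] | None:
    """Parse 'allele:count;allele:count' read-support serialization."""
    if isinstance(value, dict):
        return value
    if not isinstance(value, str) or not value:
        return None
    out: dict[int, int] = {}
    for part in value.split(";"):
        allele, count = part.split(":")
        out[int(allele)] = int(count)
    return out


def read_genotypes(path: str | Path) -> pd.DataFrame:
    g = read_table(path)
    required = {"marker_id", "individual_id", "allele1", "allele2", "gq"}
    missing = required - set(g.columns)
    if missing:
        raise ValueError(f"genotype table missing columns: {sorted(missing)}")
    if (g["allele1"] > g["allele2"]).any():
        raise ValueError("genotype alleles must be normalized (allele1 <= allele2)")
    return g


def read_config(path: str | Path) -> dict:
    """Flat key-value configuration (YAML-compatible)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat mapping")
    return cfg
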