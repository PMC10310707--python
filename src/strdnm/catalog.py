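"""STR catalog records and sequence-attribute computations.

A short tandem repeat (STR) is a genomic tract of a repeated 1-6 bp motif.
The reference repeat tract (RRT) is the interval [start, end) in the
reference; its length in bp is the primary size attribute.  Attributes
computed here — repeat purity, motif GC content, motif equivalence class,
and expected heterozygosity over an allele-frequency spectrum — are the
covariates of the downstream mutation-rate models.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class StrRecord:
    """One STR catalog entry with derived attributes.

    Coordinates are 0-based half-open (BED convention); ``rrt_length`` is
    ``end - start`` in bp.  ``purity`` is the fraction of expected motif
    copies actually observed (1.0 for a perfectly pure tract).
    """

    chrom: str
    start: int
    end: int
    motif: str
    purity: float = 1.0
    marker_id: str | None = None

    def __post_init__(self) -> None:
        self.motif = self.motif.upper()
        if not set(self.motif) <= DNA:
            raise ValueError(f"motif {self.motif!r} contains non-DNA characters")
        if not 1 <= len(self.motif) <= 6:
            raise ValueError(f"motif length must be 1..6, got {self.motif!r}")
        if self.start >= self.end:
            raise ValueError(f"start must be < end ({self.start} >= {self.end})")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.marker_id is None:
            self.marker_id = f"{self.chrom}:{self.start}-{self.end}"

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    @property
    def rrt_length(self) -> int:
        return self.end - self.start

    @property
    def gc_content(self) -> float:
        return sum(b in "GC" for b in self.motif) / len(self.motif)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif_class(motif: str) -> tuple[str, frozenset[str]]:
    """Motif equivalence class under circular shift and reverse complement.

    Two motifs describe the same repeat if one is a rotation of the other
    (the tract can be read starting anywhere) or a reverse complement (the
    tract can be read from either strand), or both composed.  Returns the
    lexicographically smallest member as the class representative together
    with the full member set.

    Classes are reported for motifs of length 1-3; longer motifs pass
    through as singleton classes.
    """
    motif = motif.upper()
    if not set(motif) <= DNA:
        raise ValueError(f"motif {motif!r} contains non-DNA characters")
    if len(motif) > 3:
        return motif, frozenset({motif})
    members = set()
    for seq in (motif, reverse_complement(motif)):
        for i in range(len(seq)):
            members.add(seq[i:] + seq[:i])
    return min(members), frozenset(members)


def compute_purity(tract_sequence: str, motif: str) -> float:
    """Repeat purity: observed motif copies / copies expected if 100% pure.

    Observed copies are counted as exact, in-frame motif matches scanning
    left to right in steps of the motif length; the expected count for a
    perfectly pure tract is floor(tract length / motif length).  Partial
    trailing copies count toward neither term.
    """
    tract_sequence = tract_sequence.upper()
    motif = motif.upper()
    m = len(motif)
    if m == 0 or len(tract_sequence) < m:
        raise ValueError("tract must be at least as long as the motif")
    expected = len(tract_sequence) // m
    observed = sum(
        tract_sequence[k * m : (k + 1) * m] == motif for k in range(expected)
    )
    return observed / expected


@dataclass
class AlleleFrequencySpectrum:
    """Allele counts at one marker over ``n`` sequences (2 x individuals)."""

    allele_counts: Mapping[int, int]

    def __post_init__(self) -> None:
        self.allele_counts = dict(self.allele_counts)
        if not self.allele_counts or any(c <= 0 for c in self.allele_counts.values()):
            raise ValueError("allele counts must be positive and non-empty")

    @property
    def n(self) -> int:
        return sum(self.allele_counts.values())

    @property
    def k(self) -> int:
        return len(self.allele_counts)

    @property
    def frequencies(self) -> np.ndarray:
        counts = np.array(list(self.allele_counts.values()), dtype=float)
        return counts / counts.sum()

    @classmethod
    def from_alleles(cls, alleles: Iterable[int]) -> "AlleleFrequencySpectrum":
        return cls(Counter(alleles))


def expected_heterozygosity(spectrum: AlleleFrequencySpectrum) -> float:
    """Nei's gene diversity with small-sample correction.

    H = [n/(n-1)] (1 - sum_i p_i^2) over the k allele frequencies p_i at a
    marker genotyped in n sequences.  Zero iff the marker is monomorphic.
    """
    n = spectrum.n
    if n < 2:
        raise ValueError("expected heterozygosity requires n >= 2 sequences")
    p = spectrum.frequencies
    return (n / (n - 1)) * (1.0 - float(np.sum(p**2)))


def polymorphism_rate(spectra: Iterable[AlleleFrequencySpectrum]) -> float:
    """Fraction of markers with at least two observed alleles."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("polymorphism rate of an empty catalog is undefined")
    return sum(s.k >= 2 for s in spectra) / len(spectra)
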