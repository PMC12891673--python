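"""Core data containers shared across the pipeline.

Genotypes are held as small integer codes per locus: for a biallelic locus
with alleles (a0, a1), the code is the count of a1 in the unordered allele
pair (0, 1 or 2); -1 means missing. The :class:`Panel` owns the locus names
and allele alphabets and converts between codes and "A/T"-style call strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class Panel:
    """Fixed SNP panel: autosomal locus names and biallelic alphabets,
    plus the sexing marker layout (Y loci amplify only in males)."""

    locus_names: tuple[str, ...]
    alleles: tuple[tuple[str, str], ...]  # (a0, a1) per locus
    n_y_markers: int = 4
    n_x_markers: int = 3

    def __post_init__(self):
        if len(self.locus_names) != len(self.alleles):
            raise ValueError("locus_names and alleles must align")
        if len(set(self.locus_names)) != len(self.locus_names):
            raise ValueError("locus names must be unique")

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def call_to_code(self, locus_index: int, call: str) -> int:
        """Parse an "A/T"-style unordered call into the 0/1/2 code."""
        if call is None or call == "":
            return MISSING
        try:
            a, b = call.split("/")
        except ValueError:
            raise ValueError(f"bad call syntax {call!r} (expected 'X/Y' or '')")
        a0, a1 = self.alleles[locus_index]
        valid = {a0, a1}
        if a not in valid or b not in valid:
            raise ValueError(
                f"call {call!r} uses alleles outside {valid} at locus "
                f"{self.locus_names[locus_index]!r}"
            )
        return (a == a1) + (b == a1)

    def code_to_call(self, locus_index: int, code: int) -> str:
        if code == MISSING:
            return ""
        a0, a1 = self.alleles[locus_index]
        return {0: f"{a0}/{a0}", 1: f"{a0}/{a1}", 2: f"{a1}/{a1}"}[int(code)]

    @classmethod
    def default(cls, n_loci: int = 85) -> "Panel":
        """The standard 85-autosomal-SNP panel with cycled allele alphabets."""
        pairs = [(a, b) for i, a in enumerate(_BASES) for b in _BASES[i + 1 :]]
        return cls(
            locus_names=tuple(f"L{i + 1:03d}" for i in range(n_loci)),
            alleles=tuple(pairs[i % len(pairs)] for i in range(n_loci)),
        )


@dataclass
class SampleRecord:
    """One genotyped fecal sample."""

    sample_id: str
    x: float
    y: float
    genotype: np.ndarray  # int8 codes, MISSING for no call
    y_calls: np.ndarray  # bool, amplification of each Y marker
    x_calls: np.ndarray  # bool, amplification of each X marker
    collection_year: int | None = None

    def __post_init__(self):
        self.genotype = np.asarray(self.genotype, dtype=np.int8)
        self.y_calls = np.asarray(self.y_calls, dtype=bool)
        self.x_calls = np.asarray(self.x_calls, dtype=bool)
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite coordinates")

    @property
    def n_called(self) -> int:
        return int(np.sum(self.genotype != MISSING))

    @property
    def y_positive(self) -> bool:
        """At least one Y marker amplified (male signal)."""
        return bool(self.y_calls.any())


@dataclass
class Individual:
    """A cluster of samples identified as one animal."""

    individual_id: str
    sex: str  # "M", "F" or "ambiguous"
    member_sample_ids: list[str]
    consensus: np.ndarray  # int8 codes
    locations: np.ndarray  # (k, 2) metres
    center: tuple[float, float]

    @property
    def n_samples(self) -> int:
        return len(self.member_sample_ids)


@dataclass
class Dyad:
    """An unordered pair of first-order-related individuals."""

    id_a: str
    id_b: str
    sex_class: str  # "MM", "FF" or "MF"
    r: float
    distance_km: float
    angle_deg: float | None  # None when the two centers coincide
    direction: str | None  # "D1" | "D2" | None
    rivers_crossed: int
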