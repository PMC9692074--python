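"""Core record types for aggregated population allele-count data.

The data object throughout the package is a *per-variant, per-population
allele-count table* in the style of gnomAD's aggregate browser output: for
every variant and population stratum we know the alternate allele count
(AC), the number of successfully genotyped chromosomes (AN) and the number
of homozygous individuals -- never individual genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .acmg import EvidenceProfile


@dataclass(frozen=True)
class PopulationCounts:
    """Aggregate counts for one variant in one population stratum.

    ``an is None`` encodes a cell that the source table reports as an
    aggregate zero without printing an allele number (common in published
    per-population tables).  A positive allele count always requires a
    concrete allele number.
    """

    ac: int
    an: Optional[int] = None
    hom: int = 0

    def __post_init__(self) -> None:
        if self.ac < 0:
            raise ValueError(f"allele count must be non-negative, got {self.ac}")
        if self.hom < 0:
            raise ValueError(f"homozygote count must be non-negative, got {self.hom}")
        if 2 * self.hom > self.ac:
            raise ValueError(
                f"homozygote count {self.hom} implies {2 * self.hom} alleles "
                f"but allele count is {self.ac}"
            )
        if self.an is None:
            if self.ac > 0:
                raise ValueError(
                    f"positive allele count {self.ac} requires an allele number"
                )
        else:
            if self.an <= 0:
                raise ValueError(f"allele number must be positive, got {self.an}")
            if self.ac > self.an:
                raise ValueError(
                    f"allele count {self.ac} exceeds allele number {self.an}"
                )

    @property
    def frequency(self) -> Optional[float]:
        """Per-site allele frequency AC/AN, or None when AN is unreported."""
        if self.an is None:
            return 0.0 if self.ac == 0 else None
        return self.ac / self.an


@dataclass(frozen=True)
class PopulationCohort:
    """A named population stratum with its diploid sample size N."""

    label: str
    n_individuals: int

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("cohort label must be non-empty")
        if self.n_individuals <= 0:
            raise ValueError(
                f"cohort size must be positive, got {self.n_individuals}"
            )

    @property
    def chromosomes(self) -> int:
        """Total chromosome count 2N."""
        return 2 * self.n_individuals


@dataclass
class VariantRecord:
    """One panel variant with per-population aggregate counts.

    Identity for deduplication purposes is ``(gene, hgvs_c)``, falling back
    to genomic coordinates when coding HGVS is unavailable.
    """

    gene: str
    hgvs_c: str
    hgvs_p: Optional[str] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None  # 1-based (VCF convention)
    ref: Optional[str] = None
    alt: Optional[str] = None
    per_population: dict[str, PopulationCounts] = field(default_factory=dict)
    qc_flags: frozenset[str] = frozenset()
    annotations: dict[str, str] = field(default_factory=dict)
    evidence: Optional["EvidenceProfile"] = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if not self.hgvs_c and not (self.chrom and self.pos and self.ref and self.alt):
            raise ValueError(
                "variant needs a coding HGVS or full genomic coordinates"
            )
        self.qc_flags = frozenset(self.qc_flags)

    @property
    def key(self) -> str:
        """Stable identifier used as mapping key throughout the pipeline."""
        if self.hgvs_c:
            return f"{self.gene}:{self.hgvs_c}"
        return f"{self.gene}:{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    def counts(self, population: str) -> Optional[PopulationCounts]:
        """Counts for ``population``, or None when the site was not observed
        (reported) in that stratum."""
        return self.per_population.get(population)

    def validate_against_cohort(self, cohort: PopulationCohort) -> None:
        """Check AN does not exceed the cohort's chromosome count 2N."""
        counts = self.per_population.get(cohort.label)
        if counts is not None and counts.an is not None:
            if counts.an > cohort.chromosomes:
                raise ValueError(
                    f"{self.key}: allele number {counts.an} exceeds 2N="
                    f"{cohort.chromosomes} for population {cohort.label!r}"
                )
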