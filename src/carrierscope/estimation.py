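"""Carrier-frequency and Hardy-Weinberg incidence estimation.

Model
-----
For an autosomal-recessive condition, let ``q_g`` be the summed frequency
of pathogenic alleles in gene ``g`` within a cohort of ``N`` diploid
individuals.  The plug-in estimator from aggregate counts is

    q_g = (sum of pathogenic allele counts in g) / (2N)

with the cohort's chromosome count 2N as denominator (per-site allele
numbers are retained on the records for diagnostics but do not enter the
estimate).  Under Hardy-Weinberg equilibrium (1 = p^2 + 2pq + q^2) the
expected affected birth fraction for gene ``g`` is ``q_g^2``, and for a
panel of genes the incidences sum:

    panel incidence = sum_g q_g^2

(compound heterozygosity across genes is negligible at these frequencies
and each gene is fully penetrant recessive).  Carrier individuals are
equated with pathogenic allele count minus homozygotes, i.e. each observed
allele outside a homozygote marks one distinct carrier -- a safe
approximation when q is small.

Uncertainty is exact-binomial throughout: Clopper-Pearson intervals on
carrier counts (out of N) and allele counts (out of 2N); incidence
intervals square the allele-frequency bounds and sum across genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import beta as _beta

from .records import PopulationCohort, VariantRecord


def clopper_pearson(
    x: int, n: int, conf: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval.

    Computed from Beta quantiles: lower = Beta(alpha/2; x, n-x+1),
    upper = Beta(1-alpha/2; x+1, n-x), with the conventional boundary
    cases lower = 0 at x = 0 and upper = 1 at x = n.
    """
    if n < 1:
        raise ValueError(f"trials must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"successes must lie in [0, {n}], got {x}")
    if not 0.0 < conf < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {conf}")
    alpha = 1.0 - conf
    low = 0.0 if x == 0 else float(_beta.ppf(alpha / 2.0, x, n - x + 1))
    high = 1.0 if x == n else float(_beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return low, high


@dataclass(frozen=True)
class GeneCarrierEstimate:
    """Per-gene carrier and allele-frequency estimate in one cohort."""

    gene: str
    cohort: PopulationCohort
    carrier_count: int           # sum over variants of (ac - hom)
    allele_count: int            # sum over variants of ac
    carrier_frequency: float     # carrier_count / N
    cf_ci: tuple[float, float]   # exact 95% CI on carrier_count / N
    q: float                     # allele_count / 2N
    q_ci: tuple[float, float]    # exact 95% CI on allele_count / 2N

    @property
    def n_individuals(self) -> int:
        return self.cohort.n_individuals

    @property
    def carrier_frequency_percent(self) -> float:
        """Carrier frequency as percent, rounded to 2 decimals (the
        reporting convention for carrier-screening tables)."""
        return round(100.0 * self.carrier_frequency, 2)


@dataclass(frozen=True)
class GeneIncidence:
    """Hardy-Weinberg incidence q^2 for one gene, with squared-bound CI."""

    incidence: float
    ci: tuple[float, float]

    @property
    def denominator(self) -> Optional[int]:
        """Reporting form 1/n; None when no alleles were observed."""
        return incidence_denominator(self.incidence)

    @property
    def ci_denominators(self) -> tuple[Optional[int], Optional[int]]:
        """(denominator of upper incidence bound, of lower bound) -- i.e.
        the interval endpoints in 1/n form, rarest last."""
        return (incidence_denominator(self.ci[1]),
                incidence_denominator(self.ci[0]))


def incidence_denominator(incidence: float) -> Optional[int]:
    """Round 1/incidence to the nearest integer; None for incidence 0."""
    if incidence == 0.0:
        return None
    return round(1.0 / incidence)


def carrier_frequency(
    carrier_count: int, cohort: PopulationCohort, conf: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Point estimate carrier_count/N with exact binomial CI."""
    if carrier_count > cohort.n_individuals:
        raise ValueError(
            f"carrier count {carrier_count} exceeds cohort size "
            f"{cohort.n_individuals}"
        )
    cf = carrier_count / cohort.n_individuals
    return cf, clopper_pearson(carrier_count, cohort.n_individuals, conf)


def gene_q(
    records: Iterable[VariantRecord], cohort: PopulationCohort
) -> float:
    """Pathogenic allele frequency q = (sum of AC) / (2N) for one gene."""
    records = list(records)
    genes = {r.gene for r in records}
    if len(genes) > 1:
        raise ValueError(f"records span multiple genes: {sorted(genes)}")
    total_ac = sum(
        c.ac for r in records
        if (c := r.per_population.get(cohort.label)) is not None
    )
    return total_ac / cohort.chromosomes


def gene_incidence(
    q: float, q_ci: tuple[float, float] = (0.0, 0.0)
) -> GeneIncidence:
    """Hardy-Weinberg incidence q^2 with CI from squared q bounds."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {q}")
    return GeneIncidence(incidence=q * q, ci=(q_ci[0] ** 2, q_ci[1] ** 2))


def estimate_gene(
    gene: str,
    records: Iterable[VariantRecord],
    cohort: PopulationCohort,
    conf: float = 0.95,
) -> GeneCarrierEstimate:
    """Full per-gene estimate from that gene's pathogenic variant records."""
    records = [r for r in records if r.gene == gene]
    allele_count = 0
    carrier_count = 0
    for rec in records:
        counts = rec.per_population.get(cohort.label)
        if counts is None:
            continue
        rec.validate_against_cohort(cohort)
        allele_count += counts.ac
        carrier_count += counts.ac - counts.hom
    cf, cf_ci = carrier_frequency(carrier_count, cohort, conf)
    q = allele_count / cohort.chromosomes
    q_ci = clopper_pearson(allele_count, cohort.chromosomes, conf)
    return GeneCarrierEstimate(
        gene=gene,
        cohort=cohort,
        carrier_count=carrier_count,
        allele_count=allele_count,
        carrier_frequency=cf,
        cf_ci=cf_ci,
        q=q,
        q_ci=q_ci,
    )


@dataclass(frozen=True)
class PanelIncidenceEstimate:
    """Panel-wide carrier frequency and summed Hardy-Weinberg incidence."""

    cohort: PopulationCohort
    per_gene: dict[str, GeneCarrierEstimate]
    per_gene_incidence: dict[str, GeneIncidence]
    zero_allele_genes: tuple[str, ...]  # observed no pathogenic alleles
    carrier_count: int
    carrier_frequency: float
    cf_ci: tuple[float, float]
    panel_incidence: float              # sum of q_g^2 over genes with q > 0
    panel_ci: tuple[float, float]       # summed squared allele-freq bounds

    @property
    def panel_denominator(self) -> Optional[int]:
        return incidence_denominator(self.panel_incidence)

    @property
    def panel_ci_denominators(self) -> tuple[Optional[int], Optional[int]]:
        return (incidence_denominator(self.panel_ci[1]),
                incidence_denominator(self.panel_ci[0]))

    @property
    def carrier_frequency_percent(self) -> float:
        return round(100.0 * self.carrier_frequency, 2)


def panel_estimate(
    gene_estimates: Sequence[GeneCarrierEstimate], conf: float = 0.95
) -> PanelIncidenceEstimate:
    """Aggregate per-gene estimates into a panel-wide estimate.

    The panel carrier count is the sum of per-gene carrier counts (one
    exact binomial CI on the summed count); the panel incidence is the sum
    of per-gene q^2 terms.  Genes with zero observed pathogenic alleles
    contribute nothing to either sum -- their incidence is not estimable
    from aggregate zeros -- and are flagged in ``zero_allele_genes``.
    """
    if not gene_estimates:
        raise ValueError("panel needs at least one gene estimate")
    cohorts = {e.cohort for e in gene_estimates}
    if len(cohorts) > 1:
        raise ValueError("gene estimates mix cohorts")
    cohort = gene_estimates[0].cohort
    genes = [e.gene for e in gene_estimates]
    if len(genes) != len(set(genes)):
        raise ValueError("duplicate gene estimates in panel")

    carrier_count = sum(e.carrier_count for e in gene_estimates)
    cf, cf_ci = carrier_frequency(carrier_count, cohort, conf)
    per_gene_incidence: dict[str, GeneIncidence] = {}
    zero_genes: list[str] = []
    inc_sum = lo_sum = hi_sum = 0.0
    for est in gene_estimates:
        inc = gene_incidence(est.q, est.q_ci)
        per_gene_incidence[est.gene] = inc
        if est.allele_count == 0:
            zero_genes.append(est.gene)
            continue
        inc_sum += inc.incidence
        lo_sum += inc.ci[0]
        hi_sum += inc.ci[1]
    return PanelIncidenceEstimate(
        cohort=cohort,
        per_gene={e.gene: e for e in gene_estimates},
        per_gene_incidence=per_gene_incidence,
        zero_allele_genes=tuple(zero_genes),
        carrier_count=carrier_count,
        carrier_frequency=cf,
        cf_ci=cf_ci,
        panel_incidence=inc_sum,
        panel_ci=(lo_sum, hi_sum),
    )


def estimate_panel(
    records: Iterable[VariantRecord],
    cohort: PopulationCohort,
    genes: Optional[Sequence[str]] = None,
    conf: float = 0.95,
) -> PanelIncidenceEstimate:
    """One-call panel estimate from pathogenic variant records.

    ``genes`` fixes the panel membership (genes without any record count
    as zero-allele genes); by default the panel is the set of genes seen
    in the records.
    """
    records = list(records)
    if genes is None:
        genes = sorted({r.gene for r in records})
    estimates = [estimate_gene(g, records, cohort, conf) for g in genes]
    return panel_estimate(estimates, conf)


def allele_share(allele_counts: Mapping[str, int]) -> dict[str, float]:
    """Fraction of the panel's pathogenic alleles carried by each gene.

    Fractions sum to 1; the conventional rendering is percent to one
    decimal.  A zero panel total is an error (no shares to apportion).
    """
    total = sum(allele_counts.values())
    if total <= 0:
        raise ValueError("panel allele total is zero; shares undefined")
    if any(c < 0 for c in allele_counts.values()):
        raise ValueError("negative allele count")
    return {gene: count / total for gene, count in allele_counts.items()}


@dataclass(frozen=True)
class PopulationProjection:
    """Expected carriers and affected births in a census population."""

    carriers: float              # cf x population size
    carrier_newborns: int        # cf x annual births, nearest integer
    affected_births: float       # incidence x annual births, 1 decimal


def project_population(
    cf: float,
    incidence: float,
    population_size: float,
    annual_births: float,
) -> PopulationProjection:
    """Project a carrier frequency and incidence onto census numbers.

    ``cf`` should be the *reported* carrier frequency (i.e. the rounded
    percent divided by 100) when reproducing published projections, since
    that is the figure such projections start from.
    """
    for name, value in (("cf", cf), ("incidence", incidence)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {value}")
    if population_size < 0 or annual_births < 0:
        raise ValueError("population sizes must be non-negative")
    return PopulationProjection(
        carriers=cf * population_size,
        carrier_newborns=round(cf * annual_births),
        affected_births=round(incidence * annual_births, 1),
    )
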