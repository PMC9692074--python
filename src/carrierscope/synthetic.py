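"""Synthetic gnomAD-like cohorts with known ground truth.

The generator emulates the aggregate structure of an exome-cohort allele
table: for each variant and population, the allele number AN is the number
of chromosomes that were successfully genotyped (2N thinned by a per-site
call rate), genotypes follow Hardy-Weinberg proportions at the true allele
frequency q, and only the aggregates (AC, AN, homozygote count) survive.
It deliberately does not model linkage, admixture, sequencing error or
site-specific call-rate covariates -- it exists so that every pipeline
stage, and the coverage of the exact binomial intervals, can be exercised
against a known truth without any download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .acmg import EvidenceProfile
from .estimation import clopper_pearson
from .records import PopulationCohort, PopulationCounts, VariantRecord

#: QC flag attached to synthetically "failed" sites.
_SYNTHETIC_QC_FLAG = "RF"


@dataclass(frozen=True)
class SyntheticVariantSpec:
    """Ground truth for one simulated variant."""

    gene: str
    hgvs_c: str
    q: dict[str, float]  # population label -> true allele frequency
    acmg_codes: str = "PVS1;PM2;PP5"
    clinvar: str = "Pathogenic"
    hgmd: str = "DM"

    def __post_init__(self) -> None:
        for pop, freq in self.q.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(
                    f"{self.gene}:{self.hgvs_c}: q[{pop!r}]={freq} outside [0, 1]"
                )


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative parameters for a gnomAD-like aggregated cohort.

    ``call_rate`` is the per-chromosome genotyping success probability;
    AN_v ~ Binomial(2N, call_rate) per site (fixed AN = 2N at call_rate 1).
    ``qc_flag_rate`` is the probability that a variant carries a QC-fail
    flag.  The same seed always reproduces the identical cohort.
    """

    populations: tuple[PopulationCohort, ...]
    variants: tuple[SyntheticVariantSpec, ...]
    call_rate: float = 1.0
    qc_flag_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.call_rate <= 1.0:
            raise ValueError(f"call_rate must be in (0, 1], got {self.call_rate}")
        if not 0.0 <= self.qc_flag_rate <= 1.0:
            raise ValueError(f"qc_flag_rate must be in [0, 1]")
        if not self.populations:
            raise ValueError("at least one population is required")


def generate_cohort(spec: SyntheticCohortSpec) -> list[VariantRecord]:
    """Draw one aggregated cohort from the generative model.

    Per variant and population with 2N chromosomes:

    * ``AN ~ Binomial(2N, call_rate)`` (exactly 2N when call_rate = 1);
    * among the ``AN // 2`` fully genotyped individuals, homozygotes are
      ``Binomial(AN//2, q^2)`` and heterozygotes ``Binomial`` among the
      remainder at the conditional Hardy-Weinberg rate ``2pq / (1 - q^2)``;
    * ``AC = 2 x hom + het``, so aggregates are always self-consistent
      (``2 hom <= AC <= AN``) and ``E[AC] ~= AN x q``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[VariantRecord] = []
    for variant in spec.variants:
        per_population: dict[str, PopulationCounts] = {}
        for cohort in spec.populations:
            q = variant.q.get(cohort.label)
            if q is None:
                continue
            two_n = cohort.chromosomes
            if spec.call_rate >= 1.0:
                an = two_n
            else:
                an = int(rng.binomial(two_n, spec.call_rate))
            if an == 0:
                continue
            n_called = an // 2
            hom = int(rng.binomial(n_called, q * q)) if n_called else 0
            remainder = n_called - hom
            if q < 1.0 and remainder > 0:
                het_rate = 2.0 * q * (1.0 - q) / (1.0 - q * q)
                het = int(rng.binomial(remainder, het_rate))
            else:
                het = 0
            # An odd AN leaves one lone chromosome, genotyped haploidly.
            lone = int(rng.binomial(1, q)) if an % 2 else 0
            ac = 2 * hom + het + lone
            per_population[cohort.label] = PopulationCounts(ac=ac, an=an, hom=hom)
        flags = frozenset()
        if spec.qc_flag_rate > 0.0 and rng.random() < spec.qc_flag_rate:
            flags = frozenset({_SYNTHETIC_QC_FLAG})
        records.append(
            VariantRecord(
                gene=variant.gene,
                hgvs_c=variant.hgvs_c,
                per_population=per_population,
                qc_flags=flags,
                annotations={"clinvar": variant.clinvar, "hgmd": variant.hgmd},
                evidence=EvidenceProfile.parse(variant.acmg_codes),
            )
        )
    return records


@dataclass(frozen=True)
class GeneRecovery:
    """Recovery diagnostics for one gene in one population."""

    gene: str
    true_q: float
    mean_q_hat: float
    bias: float            # mean(q_hat) - q
    mc_se: float           # Monte-Carlo standard error of the bias
    ci_coverage: float     # fraction of replicates whose CI covers q


@dataclass(frozen=True)
class RecoverySummary:
    """Estimator-recovery study results for one population."""

    population: str
    replicates: int
    per_gene: dict[str, GeneRecovery]
    true_panel_incidence: float
    mean_panel_incidence: float
    panel_incidence_relative_bias: float  # (mean - true) / true

    @property
    def min_coverage(self) -> float:
        return min(g.ci_coverage for g in self.per_gene.values())


def recovery_study(
    spec: SyntheticCohortSpec,
    replicates: int = 1000,
    conf: float = 0.95,
    population: Optional[str] = None,
) -> RecoverySummary:
    """Quantify bias of the plug-in estimators and exact-CI coverage.

    Repeatedly draws cohorts from ``spec``, re-estimates per-gene q as
    summed AC over 2N and the panel incidence as the summed q^2, and
    reports the bias of q-hat with its Monte-Carlo standard error, the
    empirical coverage of the Clopper-Pearson interval on the allele
    count, and the relative bias of the plug-in panel incidence (which is
    upward-biased by Var(q-hat); the study measures it rather than
    correcting it).  Deterministic under the spec's seed.
    """
    if replicates < 100:
        raise ValueError("recovery study needs >= 100 replicates")
    if population is None:
        population = spec.populations[0].label
    cohort = next(c for c in spec.populations if c.label == population)
    two_n = cohort.chromosomes

    genes: list[str] = []
    true_gene_q: dict[str, float] = {}
    for variant in spec.variants:
        if population not in variant.q:
            continue
        if variant.gene not in true_gene_q:
            genes.append(variant.gene)
            true_gene_q[variant.gene] = 0.0
        true_gene_q[variant.gene] += variant.q[population]

    q_hats = {g: np.empty(replicates) for g in genes}
    covered = {g: 0 for g in genes}
    panel_inc = np.empty(replicates)
    for rep in range(replicates):
        rep_spec = SyntheticCohortSpec(
            populations=spec.populations,
            variants=spec.variants,
            call_rate=spec.call_rate,
            qc_flag_rate=spec.qc_flag_rate,
            seed=spec.seed + rep,
        )
        records = generate_cohort(rep_spec)
        inc = 0.0
        gene_ac = {g: 0 for g in genes}
        for rec in records:
            counts = rec.per_population.get(population)
            if counts is not None and rec.gene in gene_ac:
                gene_ac[rec.gene] += counts.ac
        for g in genes:
            q_hat = gene_ac[g] / two_n
            q_hats[g][rep] = q_hat
            low, high = clopper_pearson(gene_ac[g], two_n, conf)
            if low <= true_gene_q[g] <= high:
                covered[g] += 1
            inc += q_hat * q_hat
        panel_inc[rep] = inc

    per_gene: dict[str, GeneRecovery] = {}
    for g in genes:
        mean_q = float(np.mean(q_hats[g]))
        per_gene[g] = GeneRecovery(
            gene=g,
            true_q=true_gene_q[g],
            mean_q_hat=mean_q,
            bias=mean_q - true_gene_q[g],
            mc_se=float(np.std(q_hats[g], ddof=1) / math.sqrt(replicates)),
            ci_coverage=covered[g] / replicates,
        )
    true_inc = sum(q * q for q in true_gene_q.values())
    mean_inc = float(np.mean(panel_inc))
    rel_bias = (mean_inc - true_inc) / true_inc if true_inc > 0 else 0.0
    return RecoverySummary(
        population=population,
        replicates=replicates,
        per_gene=per_gene,
        true_panel_incidence=true_inc,
        mean_panel_incidence=mean_inc,
        panel_incidence_relative_bias=rel_bias,
    )


def korean_fhlh_scenario(
    seed: int = 0, call_rate: float = 1.0
) -> SyntheticCohortSpec:
    """A Korean-cohort-like scenario: N = 1,909; per-gene true pathogenic
    allele frequencies matching the observed fHLH panel (6, 5 and 1
    alleles in PRF1, UNC13D and STXBP2 over 3,818 chromosomes)."""
    two_n = 2 * 1909
    return SyntheticCohortSpec(
        populations=(PopulationCohort("Korean", 1909),),
        variants=(
            SyntheticVariantSpec("PRF1", "sim.1", {"Korean": 6 / two_n}),
            SyntheticVariantSpec("UNC13D", "sim.2", {"Korean": 5 / two_n}),
            SyntheticVariantSpec("STXBP2", "sim.3", {"Korean": 1 / two_n}),
        ),
        call_rate=call_rate,
        seed=seed,
    )


def east_asian_fhlh_scenario(
    seed: int = 0, call_rate: float = 1.0
) -> SyntheticCohortSpec:
    """An East-Asian-cohort-like scenario: N = 9,197 with per-gene true
    frequencies matching the observed panel (14, 9, 2, 5 alleles)."""
    two_n = 2 * 9197
    return SyntheticCohortSpec(
        populations=(PopulationCohort("EastAsian", 9197),),
        variants=(
            SyntheticVariantSpec("PRF1", "sim.1", {"EastAsian": 14 / two_n}),
            SyntheticVariantSpec("UNC13D", "sim.2", {"EastAsian": 9 / two_n}),
            SyntheticVariantSpec("STX11", "sim.3", {"EastAsian": 2 / two_n}),
            SyntheticVariantSpec("STXBP2", "sim.4", {"EastAsian": 5 / two_n}),
        ),
        call_rate=call_rate,
        seed=seed,
    )


SCENARIOS = {
    "korean_fhlh": korean_fhlh_scenario,
    "east_asian_fhlh": east_asian_fhlh_scenario,
}
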