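"""Reading, validating, QC-filtering and subsetting allele-count tables.

TSV is the canonical interchange format: one row per variant with
per-population ``ac_<pop>/an_<pop>/hom_<pop>`` triplets, mirroring how
aggregate browsers publish per-population counts.  VCF ingestion (gnomAD
INFO-field dialect, ``AC_<pop>/AN_<pop>/nhomalt_<pop>``) is a convenience
layer that normalizes to the same records.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pysam

from .acmg import EvidenceProfile
from .records import PopulationCohort, PopulationCounts, VariantRecord

#: QC filter flags excluded by default, matching gnomAD's site filters:
#: excess heterozygosity (InbreedingCoeff), no high-confidence genotype
#: after filtering (AC0), and the random-forest variant QC (RF).
DEFAULT_EXCLUDED_FLAGS = frozenset({"InbreedingCoeff", "AC0", "RF"})

#: Annotation columns recognised in the canonical TSV layout.
_ANNOTATION_COLUMNS = ("clinvar", "hgmd")


@dataclass(frozen=True)
class TableSchema:
    """Column mapping for the canonical TSV layout.

    Population strata are discovered from ``ac_<pop>`` columns; each must
    be paired with ``an_<pop>``, with ``hom_<pop>`` optional (defaulting
    to zero homozygotes -- the common case for rare recessive alleles).
    """

    gene: str = "gene"
    hgvs_c: str = "hgvs_c"
    hgvs_p: str = "hgvs_p"
    flags: str = "flags"
    acmg_codes: str = "acmg_codes"
    ac_prefix: str = "ac_"
    an_prefix: str = "an_"
    hom_prefix: str = "hom_"

    def populations(self, header: Sequence[str]) -> list[str]:
        return [
            c[len(self.ac_prefix):]
            for c in header
            if c.startswith(self.ac_prefix)
        ]


DEFAULT_SCHEMA = TableSchema()


class TableFormatError(ValueError):
    """A malformed table row or header, with row/column context."""


def _parse_int(value: str, *, row: int, column: str) -> Optional[int]:
    value = value.strip()
    if value in ("", "."):
        return None
    try:
        return int(value)
    except ValueError:
        raise TableFormatError(
            f"row {row}: column {column!r} is not an integer: {value!r}"
        ) from None


def read_variant_table(
    path: Union[str, Path],
    schema: TableSchema = DEFAULT_SCHEMA,
) -> list[VariantRecord]:
    """Read a TSV allele-count table into validated records.

    Empty ``ac`` cells mean the population did not observe (report) the
    site and it is left out of ``per_population``; ``ac=0`` with an empty
    ``an`` records an aggregate zero whose allele number the source did
    not print.  Missing ``hom`` defaults to 0.  Validation failures name
    the offending row and column.
    """
    path = Path(path)
    records: list[VariantRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for required in (schema.gene, schema.hgvs_c):
            if required not in header:
                raise TableFormatError(f"missing required column {required!r}")
        populations = schema.populations(header)
        if not populations:
            raise TableFormatError(
                f"no per-population allele-count columns ({schema.ac_prefix}<pop>) found"
            )
        for pop in populations:
            if f"{schema.an_prefix}{pop}" not in header:
                raise TableFormatError(
                    f"population {pop!r} has {schema.ac_prefix}{pop} but no "
                    f"{schema.an_prefix}{pop} column"
                )
        for idx, row in enumerate(reader, start=2):  # 1-based incl. header
            gene = (row.get(schema.gene) or "").strip()
            hgvs_c = (row.get(schema.hgvs_c) or "").strip()
            if not gene:
                raise TableFormatError(f"row {idx}: column {schema.gene!r} is empty")
            per_population: dict[str, PopulationCounts] = {}
            for pop in populations:
                ac = _parse_int(row.get(f"{schema.ac_prefix}{pop}", ""),
                                row=idx, column=f"{schema.ac_prefix}{pop}")
                if ac is None:
                    continue
                an = _parse_int(row.get(f"{schema.an_prefix}{pop}", ""),
                                row=idx, column=f"{schema.an_prefix}{pop}")
                hom = _parse_int(row.get(f"{schema.hom_prefix}{pop}", ""),
                                 row=idx, column=f"{schema.hom_prefix}{pop}") or 0
                try:
                    per_population[pop] = PopulationCounts(ac=ac, an=an, hom=hom)
                except ValueError as exc:
                    raise TableFormatError(
                        f"row {idx}: population {pop!r}: {exc}"
                    ) from None
            flags = frozenset(
                t.strip()
                for t in (row.get(schema.flags) or "").split(",")
                if t.strip()
            )
            annotations = {
                key: row[key].strip()
                for key in _ANNOTATION_COLUMNS
                if row.get(key, "").strip()
            }
            codes = (row.get(schema.acmg_codes) or "").strip()
            evidence = EvidenceProfile.parse(codes) if codes else None
            records.append(
                VariantRecord(
                    gene=gene,
                    hgvs_c=hgvs_c,
                    hgvs_p=(row.get(schema.hgvs_p) or "").strip() or None,
                    per_population=per_population,
                    qc_flags=flags,
                    annotations=annotations,
                    evidence=evidence,
                )
            )
    return records


def write_variant_table(
    records: Iterable[VariantRecord],
    path: Union[str, Path],
    schema: TableSchema = DEFAULT_SCHEMA,
) -> None:
    """Write records back to the canonical TSV layout (inverse of
    :func:`read_variant_table`; ac/an/hom round-trip bit-exactly)."""
    records = list(records)
    populations: list[str] = []
    for rec in records:
        for pop in rec.per_population:
            if pop not in populations:
                populations.append(pop)
    header = [schema.gene, schema.hgvs_c, schema.hgvs_p, schema.flags,
              *_ANNOTATION_COLUMNS, schema.acmg_codes]
    for pop in populations:
        header += [f"{schema.ac_prefix}{pop}", f"{schema.an_prefix}{pop}",
                   f"{schema.hom_prefix}{pop}"]
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for rec in records:
            row = [
                rec.gene,
                rec.hgvs_c,
                rec.hgvs_p or "",
                ",".join(sorted(rec.qc_flags)),
                rec.annotations.get("clinvar", ""),
                rec.annotations.get("hgmd", ""),
                str(rec.evidence) if rec.evidence is not None else "",
            ]
            for pop in populations:
                counts = rec.per_population.get(pop)
                if counts is None:
                    row += ["", "", ""]
                else:
                    row += [
                        str(counts.ac),
                        "" if counts.an is None else str(counts.an),
                        str(counts.hom),
                    ]
            writer.writerow(row)


def read_vcf_panel(
    path: Union[str, Path],
    panel: Sequence[str],
    pop_fields: Mapping[str, str],
    gene_info_key: str = "GENE",
) -> list[VariantRecord]:
    """Read a gnomAD-dialect VCF restricted to a gene panel.

    ``pop_fields`` maps population labels to the INFO-field suffix used in
    the VCF (e.g. ``{"EastAsian": "eas"}`` reads ``AC_eas``/``AN_eas``/
    ``nhomalt_eas``).  Multi-allelic sites decompose into one record per
    alternate allele.  A missing AN field for a requested population is an
    explicit error, never a silent zero.
    """
    panel_set = set(panel)
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for site in vcf:
            gene = site.info.get(gene_info_key)
            if isinstance(gene, tuple):
                gene = gene[0]
            if gene not in panel_set:
                continue
            flags = frozenset(f for f in site.filter.keys() if f != "PASS")
            n_alts = len(site.alts or ())
            for alt_idx in range(n_alts):
                per_population: dict[str, PopulationCounts] = {}
                for label, suffix in pop_fields.items():
                    an_key, ac_key = f"AN_{suffix}", f"AC_{suffix}"
                    if an_key not in site.info:
                        raise KeyError(
                            f"{path}: INFO field {an_key!r} required for "
                            f"population {label!r} is absent at "
                            f"{site.chrom}:{site.pos}"
                        )
                    an = int(_scalar(site.info[an_key]))
                    ac = int(_per_alt(site.info.get(ac_key, 0), alt_idx))
                    hom = int(_per_alt(site.info.get(f"nhomalt_{suffix}", 0), alt_idx))
                    if an == 0:
                        # Site unobserved in this stratum; leave it absent
                        # rather than claiming certainty of frequency zero.
                        continue
                    per_population[label] = PopulationCounts(ac=ac, an=an, hom=hom)
                hgvs = site.info.get("HGVSC")
                if isinstance(hgvs, tuple):
                    hgvs = hgvs[alt_idx] if alt_idx < len(hgvs) else hgvs[0]
                records.append(
                    VariantRecord(
                        gene=str(gene),
                        hgvs_c=str(hgvs) if hgvs else "",
                        chrom=site.chrom,
                        pos=site.pos,
                        ref=site.ref,
                        alt=site.alts[alt_idx],
                        per_population=per_population,
                        qc_flags=flags,
                    )
                )
    return records


def _scalar(value) -> float:
    if isinstance(value, tuple):
        return value[0]
    return value


def _per_alt(value, alt_idx: int) -> float:
    if isinstance(value, tuple):
        return value[alt_idx]
    return value


def apply_qc_filter(
    records: Iterable[VariantRecord],
    excluded_flags: Iterable[str] = DEFAULT_EXCLUDED_FLAGS,
) -> list[VariantRecord]:
    """Drop records carrying any excluded QC flag; order preserved.

    Idempotent: filtering an already-filtered list is the identity.
    """
    excluded = frozenset(excluded_flags)
    return [r for r in records if not (r.qc_flags & excluded)]


def subset_population(
    records: Iterable[VariantRecord],
    cohort: PopulationCohort,
) -> list[tuple[VariantRecord, int, int]]:
    """Restrict to variants observed (AC > 0) in ``cohort``.

    Returns ``(record, ac, an)`` triples.  Sites with AC = 0 -- or
    unreported in the stratum -- are excluded: absence of observed alleles
    is not evidence of frequency zero with certainty.
    """
    records = list(records)
    available: set[str] = set()
    for r in records:
        available |= r.per_population.keys()
    if cohort.label not in available:
        raise KeyError(
            f"population {cohort.label!r} not present in any record; "
            f"available: {sorted(available)}"
        )
    out: list[tuple[VariantRecord, int, int]] = []
    for rec in records:
        counts = rec.per_population.get(cohort.label)
        if counts is None or counts.ac == 0:
            continue
        rec.validate_against_cohort(cohort)
        assert counts.an is not None  # ac > 0 guarantees a concrete AN
        out.append((rec, counts.ac, counts.an))
    return out
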