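"""Rendering of summary and per-variant tables.

Two table shapes are produced: a per-source summary (variant count,
carrier individuals, carrier frequency with CI, incidence in 1/n form
with CI) and a per-variant, per-population table whose cells read
``frequency (ac/an)``.  Rendering is a pure function of the estimates --
no number is recomputed here, only formatted.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass
from math import floor, log10
from typing import Iterable, Optional, Sequence, TextIO

import pandas as pd

from .estimation import PanelIncidenceEstimate
from .records import VariantRecord


def format_frequency(value: float, sig: int = 4) -> str:
    """Fixed-point rendering at ``sig`` significant figures (no scientific
    notation), the conventional style of per-population frequency tables;
    e.g. 3/3816 -> ``0.0007862``."""
    if value == 0:
        return "0"
    digits = max(0, sig - 1 - floor(log10(abs(value))))
    return f"{value:.{digits}f}"


def format_incidence(denominator: Optional[int]) -> str:
    """``1/n`` with thousands separators; zero-allele genes render as
    not estimable."""
    if denominator is None:
        return "NE"
    return f"1/{denominator:,}"


def _format_ci_percent(ci: tuple[float, float]) -> str:
    lo, hi = (100.0 * b for b in ci)
    # Match the usual table style: two decimals, trimming to the
    # precision that distinguishes the bounds (1.10 prints as 1.1).
    def fmt(v: float) -> str:
        s = f"{v:.2f}"
        return s.rstrip("0").rstrip(".") if "." in s and v >= 1 else s
    return f"{fmt(lo)}-{fmt(hi)}"


@dataclass(frozen=True)
class SummaryRow:
    """One per-source, per-cohort summary line."""

    source: str
    cohort: str
    n_variants: int
    carrier_individuals: int
    cf_percent: float
    cf_ci_percent: str
    incidence: str
    incidence_ci: str


def summarize(
    estimate: PanelIncidenceEstimate, source: str, n_variants: int
) -> SummaryRow:
    lo_den, hi_den = estimate.panel_ci_denominators
    return SummaryRow(
        source=source,
        cohort=estimate.cohort.label,
        n_variants=n_variants,
        carrier_individuals=estimate.carrier_count,
        cf_percent=estimate.carrier_frequency_percent,
        cf_ci_percent=_format_ci_percent(estimate.cf_ci),
        incidence=format_incidence(estimate.panel_denominator),
        incidence_ci=(
            f"{format_incidence(lo_den)} - {format_incidence(hi_den)}"
            if lo_den is not None
            else "NE"
        ),
    )


def render_summary(
    rows: Sequence[SummaryRow], fmt: str = "tsv"
) -> str:
    """Render summary rows as ``tsv``, ``json`` or ``markdown``."""
    frame = pd.DataFrame(
        {
            "Source": [r.source for r in rows],
            "Cohort": [r.cohort for r in rows],
            "Variants (n)": [r.n_variants for r in rows],
            "Carriers (n)": [r.carrier_individuals for r in rows],
            "Carrier frequency (%) (95% CI)": [
                f"{r.cf_percent:.2f} ({r.cf_ci_percent})" for r in rows
            ],
            "Estimated incidence (1/n) (95% CI)": [
                f"{r.incidence} ({r.incidence_ci})" for r in rows
            ],
        }
    )
    return _render_frame(frame, fmt)


def render_variant_table(
    records: Iterable[VariantRecord],
    populations: Sequence[str],
    fmt: str = "tsv",
) -> str:
    """Per-variant table with ``frequency (ac/an)`` cells per population.

    Aggregate-zero cells render ``0``; strata where the site is
    unobserved render ``.`` -- a distinct state, since an unreported site
    carries no evidence of frequency zero.
    """
    data: dict[str, list[str]] = {
        "Gene": [],
        "Nucleotide change": [],
        "Amino acid change": [],
    }
    for pop in populations:
        data[pop] = []
    for rec in records:
        data["Gene"].append(rec.gene)
        data["Nucleotide change"].append(rec.hgvs_c)
        data["Amino acid change"].append(rec.hgvs_p or "")
        for pop in populations:
            counts = rec.counts(pop)
            if counts is None:
                data[pop].append(".")
            elif counts.ac == 0:
                data[pop].append("0")
            else:
                freq = format_frequency(counts.ac / counts.an)
                data[pop].append(f"{freq} ({counts.ac}/{counts.an:,})")
    return _render_frame(pd.DataFrame(data), fmt)


def _render_frame(frame: pd.DataFrame, fmt: str) -> str:
    if fmt == "tsv":
        return frame.to_csv(sep="\t", index=False)
    if fmt == "json":
        return json.dumps(frame.to_dict(orient="records"), indent=2) + "\n"
    if fmt == "markdown":
        return frame.to_markdown(index=False) + "\n"
    raise ValueError(f"unknown output format {fmt!r}")


def log_run(
    excluded: Sequence[VariantRecord],
    source: str,
    stream: TextIO = sys.stderr,
) -> None:
    """Audit log: which variants QC exclusion removed, and the
    classification source in force."""
    print(f"classification source: {source}", file=stream)
    if excluded:
        print(f"QC-excluded variants ({len(excluded)}):", file=stream)
        for rec in excluded:
            print(f"  {rec.key} [{','.join(sorted(rec.qc_flags))}]", file=stream)
    else:
        print("QC-excluded variants: none", file=stream)
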