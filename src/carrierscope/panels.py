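"""Packaged gene panels and reference cohorts.

The bundled familial hemophagocytic lymphohistiocytosis (fHLH) panel
covers the four autosomal-recessive fHLH genes (PRF1, UNC13D, STX11,
STXBP2) with the 19 pathogenic / likely pathogenic variants observed in
the gnomAD v2.1.1 East Asian exomes, including their per-population
allele counts and illustrative ACMG/AMP evidence profiles consistent
with each variant's pathogenic / likely pathogenic call.
"""

from __future__ import annotations

from importlib import resources

from .io_variants import read_variant_table
from .records import PopulationCohort, VariantRecord

#: The four fHLH panel genes.
FHLH_GENES = ("PRF1", "UNC13D", "STX11", "STXBP2")

#: gnomAD v2.1.1 exome cohort sizes for the strata in the bundled table.
EAST_ASIAN = PopulationCohort("EastAsian", 9197)
KOREAN = PopulationCohort("Korean", 1909)

COHORTS = {
    "EastAsian": EAST_ASIAN,
    "Korean": KOREAN,
    "African": PopulationCohort("African", 8128),
    "Latino": PopulationCohort("Latino", 17296),
    "AshkenaziJewish": PopulationCohort("AshkenaziJewish", 5040),
    "EuropeanFinnish": PopulationCohort("EuropeanFinnish", 10824),
    "EuropeanNonFinnish": PopulationCohort("EuropeanNonFinnish", 56885),
    "Other": PopulationCohort("Other", 3070),
    "SouthAsian": PopulationCohort("SouthAsian", 15308),
}


def fhlh_panel() -> list[VariantRecord]:
    """The bundled 19-variant fHLH pathogenic/likely-pathogenic panel."""
    ref = resources.files("carrierscope.data").joinpath("fhlh_panel.tsv")
    with resources.as_file(ref) as path:
        return read_variant_table(path)
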