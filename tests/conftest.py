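import pytest

import carrierscope as cs


@pytest.fixture(scope="session")
def panel():
    """The bundled 19-variant fHLH pathogenic/likely-pathogenic panel."""
    return cs.fhlh_panel()


@pytest.fixture(scope="session")
def pathogenic_panel(panel):
    """Panel after QC filtering and ACMG classification (all 19 select)."""
    kept = cs.apply_qc_filter(panel)
    calls = cs.classify_panel(kept, "acmg2015")
    return cs.select_pathogenic(kept, calls)


@pytest.fixture(scope="session")
def korean():
    return cs.KOREAN


@pytest.fixture(scope="session")
def east_asian():
    return cs.EAST_ASIAN


_VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=10>
##FILTER=<ID=RF,Description="Random forest QC fail">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=HGVSC,Number=A,Type=String,Description="Coding HGVS">
##INFO=<ID=AC_eas,Number=A,Type=Integer,Description="EAS allele count">
##INFO=<ID=AN_eas,Number=1,Type=Integer,Description="EAS allele number">
##INFO=<ID=nhomalt_eas,Number=A,Type=Integer,Description="EAS homozygotes">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
10\t1000\t.\tA\tT\t.\tPASS\tGENE=PRF1;HGVSC=c.100A>T;AC_eas=3;AN_eas=1000;nhomalt_eas=0
10\t2000\t.\tG\tA,C\t.\tPASS\tGENE=UNC13D;HGVSC=c.200G>A,c.200G>C;AC_eas=2,1;AN_eas=500;nhomalt_eas=0,0
10\t3000\t.\tC\tT\t.\tRF\tGENE=OTHERGENE;HGVSC=c.300C>T;AC_eas=5;AN_eas=800;nhomalt_eas=1
"""


@pytest.fixture
def toy_vcf(tmp_path):
    """A 3-site gnomAD-dialect VCF: one biallelic panel site, one
    multi-allelic panel site, one off-panel site."""
    path = tmp_path / "toy.vcf"
    path.write_text(_VCF_TEXT)
    return path
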