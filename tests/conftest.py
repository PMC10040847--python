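import pytest
from hypothesis import HealthCheck, settings

from exomark import PipelineConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def tiny_vcf(tmp_path):
    """A hand-written single-sample VCF with one biallelic SNV at 5% VAF."""
    text = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##INFO=<ID=GLOBAL_AF,Number=A,Type=Float,Description="Global population AF">
##INFO=<ID=SAS_AF,Number=A,Type=Float,Description="South-Asian population AF">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
chr1\t12345\t.\tA\tG\t.\tPASS\tGLOBAL_AF=0.005;GENE=EGFR\tGT:DP:AD\t0/1:200:190,10
"""
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def multiallelic_vcf(tmp_path):
    """One VCF line with two ALT alleles (must split into two records)."""
    text = """##fileformat=VCFv4.2
##contig=<ID=chr7>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
chr7\t5000\t.\tC\tT,G\t.\tPASS\t.\tGT:DP:AD\t1/2:100:60,25,15
"""
    path = tmp_path / "multi.vcf"
    path.write_text(text)
    return path
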