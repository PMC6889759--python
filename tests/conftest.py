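import pytest

from panagrokit import core_io, synthetic_data


@pytest.fixture
def species_tree():
    """The default six-species study tree (three parthenogens, outgroup)."""
    return core_io.read_tree(synthetic_data.DEFAULT_SPECIES_TREE)


@pytest.fixture
def quartet_tree():
    return core_io.read_tree("((A,B)ab,(C,D)cd)root;")


@pytest.fixture
def hgt_fixture():
    return synthetic_data.simulate_hit_evidence(
        synthetic_data.HgtSimSpec(n_native=10, n_hgt=5, n_contaminant=3, seed=11)
    )


VCF_TEXT = "\n".join(
    [
        "##fileformat=VCFv4.2",
        "##contig=<ID=ctg1,length=10000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1",
        "ctg1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:12,8",
        "ctg1\t200\t.\tC\tT,G\t.\tPASS\t.\tGT:AD\t0/1:5,3,2",
        "ctg1\t300\t.\tG\tA\t.\tPASS\t.\tGT:AD\t0/1:20,10",
    ]
) + "\n"


@pytest.fixture
def vcf_path(tmp_path):
    """Three-record VCF: two biallelic SNVs and one triallelic site."""
    path = tmp_path / "sites.vcf"
    path.write_text(VCF_TEXT)
    return path
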