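import textwrap

import numpy as np
import pytest

from fascimap.io_formats import AlleleDepthRecord, GeneModel


@pytest.fixture
def toy_vcf(tmp_path):
    """Three biallelic sites + one triallelic, two pools and a parent."""
    body = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
        ##contig=<ID=chr4>
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tmut_pool\twt_pool\tparent
        chr4\t100\t.\tA\tT\t.\tPASS\t.\tGT:AD\t./.:10,30\t./.:20,10\t1/1:0,15
        chr4\t200\t.\tG\tC\t.\tPASS\t.\tGT:AD\t./.:0,44\t./.:30,15\t1/1:0,12
        chr4\t300\t.\tT\tA,G\t.\tPASS\t.\tGT:AD\t./.:5,5,5\t./.:5,5,5\t1/1:0,9,0
        chr4\t400\t.\tC\tG\t.\tPASS\t.\tGT:AD\t./.:25,25\t./.:40,0\t0/1:6,6
        """
    )
    path = tmp_path / "toy.vcf"
    path.write_text(body)
    return path


@pytest.fixture
def toy_records():
    """Six records exercising every filter rule."""

    def rec(pos, parent_gt="hom_alt", dm=(10, 30), dw=(20, 10)):
        return AlleleDepthRecord(
            chrom="chr4", pos=pos, ref_allele="A", alt_allele="T",
            depth_mut_ref=dm[0], depth_mut_alt=dm[1],
            depth_wt_ref=dw[0], depth_wt_alt=dw[1], parent_gt=parent_gt,
        )

    return [
        rec(100),
        rec(200),
        rec(300, parent_gt="het"),
        rec(400, dw=(1, 2)),  # wt depth 3
        rec(500),
        rec(600),
    ]


@pytest.fixture
def toy_gene_models():
    return [
        GeneModel("gA", "chr4", 4_700_000, 4_705_000),
        GeneModel("gB", "chr4", 8_000_000, 8_003_000),
        GeneModel("gC", "chr4", 11_259_000, 11_300_000),  # straddles region end
        GeneModel("gD", "chr4", 20_000_000, 20_005_000),
        GeneModel("gE", "chr1", 5_000_000, 5_005_000),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
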