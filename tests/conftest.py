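import pytest

from clincov import (
    ConstantDepth,
    FixtureSpec,
    GeneLayout,
    PiecewiseDepth,
    make_fixture,
)


@pytest.fixture(scope="session")
def constant_fixture(tmp_path_factory):
    """Constant depth 20 everywhere; 10 germline + 10 somatic exonic loci."""
    spec = FixtureSpec(
        chrom_lengths={"chr1": 5000},
        depth_model=ConstantDepth(20),
        genes=[
            GeneLayout("GENEA", "chr1", ((1000, 1200), (2000, 2150), (3000, 3100))),
        ],
        germline=[("chr1", p) for p in range(1010, 1110, 10)],
        somatic=[("chr1", p) for p in range(2010, 2110, 10)],
        threshold=15,
    )
    return spec, make_fixture(spec, tmp_path_factory.mktemp("constant"))


@pytest.fixture(scope="session")
def piecewise_fixture(tmp_path_factory):
    """Bimodal germline depths {5,5,50,50}, constant somatic depths {7,7,7}."""
    spec = FixtureSpec(
        chrom_lengths={"chr1": 2000, "chr2": 1000},
        depth_model=PiecewiseDepth(
            {
                "chr1": [(100, 110, 5), (200, 210, 50), (300, 400, 7)],
                "chr2": [(0, 500, 30)],
            }
        ),
        genes=[GeneLayout("G1", "chr1", ((100, 120), (200, 220)))],
        germline=[("chr1", 105), ("chr1", 106), ("chr1", 205), ("chr1", 206)],
        somatic=[("chr1", 305), ("chr1", 306), ("chr1", 307)],
        threshold=15,
    )
    return spec, make_fixture(spec, tmp_path_factory.mktemp("piecewise"))
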