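import numpy as np
import pytest

from citniche.parallelism import GeneLink, MutationRecord


@pytest.fixture
def toy_mutation_records():
    """Ten records exercising every branch of the qualifying filter.

    3 nonsynonymous single-gene SNPs, 2 synonymous SNPs, 1 two-gene
    deletion, 2 single-gene IS insertions (one coding, one in-window
    promoter), 1 ambiguous intergenic event, 1 unannotated record:
    exactly 5 should qualify.
    """
    mk = lambda clone, trt, pos, typ, elem, links: MutationRecord(
        clone_id=clone, treatment=trt, position=pos, type=typ,
        element=elem, genes_affected=links,
    )
    coding = lambda g: (GeneLink(g, "coding"),)
    return [
        mk("c1", "DM0", 100, "snp_nonsynonymous", "", coding("gltA")),
        mk("c1", "DM0", 200, "snp_nonsynonymous", "", coding("yhiO")),
        mk("c2", "DM25", 300, "snp_nonsynonymous", "", coding("aceB")),
        mk("c2", "DM25", 400, "snp_synonymous", "", coding("gltA")),
        mk("c1", "DM0", 500, "snp_synonymous", "", coding("menC")),
        mk("c2", "DM25", 600, "deletion", "",
           (GeneLink("fadL", "coding"), GeneLink("fadA", "coding"))),
        mk("c1", "DM0", 700, "is_insertion", "IS150", coding("yhiO")),
        mk("c2", "DM25", 800, "is_insertion", "IS150",
           (GeneLink("menC", "promoter", 40),)),
        mk("c1", "DM0", 900, "snp_intergenic", "",
           (GeneLink("fadL", "promoter", 60), GeneLink("fadR", "promoter", 90))),
        mk("c2", "DM25", 1000, "snp_nonsynonymous", "", ()),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
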