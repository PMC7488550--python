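import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_annotation():
    """Five SNPs, three retained models with hand-set posterior mass."""
    from ptwas.annotations import AssociationModel, GeneAnnotation, SnpRecord

    models = [
        AssociationModel(frozenset({"s1"}), 0.5),
        AssociationModel(frozenset({"s1", "s3"}), 0.3),
        AssociationModel(frozenset({"s2"}), 0.15),
        AssociationModel(frozenset(), 0.05),
    ]
    pips = {"s1": 0.8, "s2": 0.15, "s3": 0.3, "s4": 0.0, "s5": 0.0}
    snps = [
        SnpRecord(f"s{i}", position=100 * i, effect_allele="A",
                  other_allele="G", pip=pips[f"s{i}"])
        for i in range(1, 6)
    ]
    return GeneAnnotation("geneA", "liver", snps, models, [])
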