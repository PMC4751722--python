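import pandas as pd
import pytest

from ploidycross.genotype_io import (
    GenotypeTable,
    IndividualRecord,
    LocusGenotype,
    Role,
)
from ploidycross.private_alleles import PrivateAlleleMatrix


def _ind(sample_id, role, genotypes, ploidy=None):
    return IndividualRecord(
        sample_id,
        role,
        {loc: LocusGenotype(loc, frozenset(a)) for loc, a in genotypes.items()},
        ploidy_label=ploidy,
    )


@pytest.fixture
def toy_table():
    """A fully informative 2-locus cross with two offspring.

    Parents are disjoint at both loci so every parental allele is private:
    dam {180,184}/{200,204}, sire {190,196}/{210,216}.
    """
    return GenotypeTable([
        _ind("D", Role.DAM, {"L1": {180, 184}, "L2": {200, 204}}),
        _ind("S", Role.SIRE, {"L1": {190, 196}, "L2": {210, 216}}),
        _ind("O1", Role.OFFSPRING, {"L1": {180, 190}, "L2": {200, 210}}),
        _ind("O2", Role.OFFSPRING, {"L1": {180, 184, 196}, "L2": {204, 216}}),
    ])


def make_individual(sample_id, role, genotypes, ploidy=None):
    return _ind(sample_id, role, genotypes, ploidy)


@pytest.fixture
def s1_style_counts():
    """SYNTHETIC stand-in for a supplementary private-allele count table.

    Fabricated per-locus values whose group totals match the published
    summary statistics of the sturgeon cross (dam-private totals 35 in the
    5n group and 63 in the 7n group, 1.8-fold; sire-private counts equal
    per locus).  The true per-locus values are only in the supplementary
    file and are not reproduced here.
    """
    loci = [f"L{i + 1:02d}" for i in range(8)]
    dam_5n = [4, 5, 4, 5, 4, 4, 5, 4]  # total 35
    dam_7n = [8, 9, 8, 8, 8, 7, 8, 7]  # total 63
    sire = [3, 2, 3, 2, 3, 3, 2, 2]  # identical in both groups
    rows = []
    for i, locus in enumerate(loci):
        rows.append({"locus": locus, "group": "5n", "parent": "DAM", "count": dam_5n[i]})
        rows.append({"locus": locus, "group": "5n", "parent": "SIRE", "count": sire[i]})
        rows.append({"locus": locus, "group": "7n", "parent": "DAM", "count": dam_7n[i]})
        rows.append({"locus": locus, "group": "7n", "parent": "SIRE", "count": sire[i]})
    return PrivateAlleleMatrix(
        loci=loci,
        groups={"5n": [], "7n": []},
        counts=pd.DataFrame(rows, columns=["locus", "group", "parent", "count"]),
    )
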