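"""Simulation of a polyploid sturgeon cross with known ground truth.

The simulator emulates a functional tetraploid (4n) dam crossed with a
functional hexaploid (6n) sire at unlinked polymorphic microsatellite loci,
the setting in which spontaneous heptaploid progeny have been observed in
cultured Siberian sturgeon.  Meiosis is modelled as polysomic: a reduced
gamete takes a uniformly random half of the homologs at each locus,
independently across loci (one locus per chromosome, no preferential
pairing, no double reduction).

Unreduced oocytes arise through two arms:

``PB2_RETENTION``
    second-division restitution — the oocyte keeps both products of
    meiosis II.  Sister chromatids are identical at centromere-proximal
    loci and may differ distal to a crossover; rather than tracking
    chiasmata, each duplicated copy is independently replaced, with
    per-locus probability ``r``, by the allele of a uniformly chosen
    non-selected homolog ("crossover-restored heterozygosity").  ``r = 0``
    gives fully homozygous duplication; ``r = 1`` approaches the allele
    diversity of two independent reduced gametes.

``APOMIXIS_CLONE``
    apomixis or premeiotic endomitosis — both yield unreduced oocytes
    genetically identical to the dam, so they share one simulator arm.

Polyspermy is modelled as dispermy (two independent reduced sperm).
Observation is presence-only: a genotype is the set of distinct allele
lengths among the copies, with optional per-allele dropout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeTable, IndividualRecord, LocusGenotype, Role

__all__ = [
    "GameteModel",
    "AlleleCopy",
    "TrueGenome",
    "CrossConfig",
    "baerii_cross_config",
    "simulate_parent",
    "form_male_gamete",
    "form_female_gamete",
    "fertilize",
    "observe_genotype",
    "simulate_cross",
    "simulate_dna_content",
    "simulate_measurements",
    "mechanism_label",
]


class GameteModel(str, Enum):
    NORMAL = "NORMAL"
    PB2_RETENTION = "PB2_RETENTION"
    APOMIXIS_CLONE = "APOMIXIS_CLONE"


class AlleleCopy(NamedTuple):
    """One allele copy, tagged by homolog of origin and parent of origin."""

    allele: int
    homolog: int
    parent: str  # "DAM" or "SIRE"


@dataclass
class TrueGenome:
    """Simulator-internal genome: per-locus allele copies with origin tags.

    ``functional_ploidy`` is the number of copies at every locus (the
    functional n-multiplier on the re-diploidised sturgeon scale).
    """

    functional_ploidy: int
    loci: dict[str, list[AlleleCopy]]

    def __post_init__(self) -> None:
        for locus, copies in self.loci.items():
            if len(copies) != self.functional_ploidy:
                raise ValueError(
                    f"locus {locus!r}: {len(copies)} copies != "
                    f"functional ploidy {self.functional_ploidy}"
                )

    def distinct_alleles(self, locus: str) -> frozenset[int]:
        return frozenset(c.allele for c in self.loci[locus])


# Per-functional-set DNA content (pg) implied by the measured pentaploid
# sibs (8.98 pg / 5); the heptaploids imply 15.02 / 7 ≈ 2.146 — the two are
# inconsistent, so the reference is always an explicit input downstream.
DEFAULT_PG_PER_SET = 1.796


@dataclass
class CrossConfig:
    """Configuration of one simulated cross.

    ``n_offspring`` offspring are produced under ``female_model`` /
    ``n_sperm`` (the focal arm), preceded by ``n_normal_offspring`` siblings
    from normally reduced oocytes and monospermic fertilization — so a single
    cross can mix normal and anomalous progeny, as observed in practice
    (143 pentaploid and 7 heptaploid sibs from one mating).

    ``r`` is the per-locus probability that a duplicated copy in a
    PB2-retained oocyte is restored to a non-selected homolog's allele;
    it subsumes centromere–locus map distance.  The default 0.8 reflects
    the high effective recombination implied by the observed ~1.8-fold
    private-allele increase (see :func:`ploidycross.private_alleles.calibrate_r`).

    ``allele_pool_size`` alleles per locus are available to the parents;
    8 loci selected for parental polymorphism and a pool of 10 distinct
    lengths per locus give parents with several private alleles each,
    mirroring informative microsatellite panels.
    """

    dam_ploidy: int = 4
    sire_ploidy: int = 6
    n_loci: int = 8
    allele_pool_size: int = 10
    r: float = 0.8
    female_model: GameteModel = GameteModel.NORMAL
    n_sperm: int = 1
    n_offspring: int = 150
    n_normal_offspring: int = 0
    observation_dropout: float = 0.0
    per_set_pg: float = DEFAULT_PG_PER_SET
    dna_cv: float = 0.02
    n_nuclei: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dam_ploidy < 2 or self.dam_ploidy % 2:
            raise ValueError("dam_ploidy must be even and >= 2")
        if self.sire_ploidy < 2 or self.sire_ploidy % 2:
            raise ValueError("sire_ploidy must be even and >= 2")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must be in [0, 1]")
        if self.n_sperm not in (1, 2):
            raise ValueError("n_sperm must be 1 (monospermic) or 2 (dispermic)")
        if not 0.0 <= self.observation_dropout < 1.0:
            raise ValueError("observation_dropout must be in [0, 1)")
        if isinstance(self.female_model, str):
            self.female_model = GameteModel(self.female_model)

    def locus_ids(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_loci)]

    def allele_pools(self) -> dict[str, list[int]]:
        """Deterministic dinucleotide ladders, one non-overlapping per locus."""
        pools = {}
        for i, locus in enumerate(self.locus_ids()):
            base = 100 + 40 * i
            pools[locus] = [base + 2 * j for j in range(self.allele_pool_size)]
        return pools


def baerii_cross_config(seed: int = 0, **overrides) -> CrossConfig:
    """The study cross: 143 pentaploid sibs plus 7 heptaploids from
    second-polar-body retention, 8 informative loci."""
    params = dict(
        female_model=GameteModel.PB2_RETENTION,
        n_offspring=7,
        n_normal_offspring=143,
        seed=seed,
    )
    params.update(overrides)
    return CrossConfig(**params)


def simulate_parent(
    ploidy: int,
    loci: Sequence[str],
    allele_pool: Mapping[str, Sequence[int]],
    rng: np.random.Generator,
    parent_tag: str,
) -> TrueGenome:
    """Draw a parental genome: each homolog takes one allele uniformly from
    the locus pool (with replacement across homologs)."""
    genome: dict[str, list[AlleleCopy]] = {}
    for locus in loci:
        pool = list(allele_pool[locus])
        if not pool:
            raise ValueError(f"locus {locus!r}: empty allele pool")
        picks = rng.integers(0, len(pool), size=ploidy)
        genome[locus] = [
            AlleleCopy(int(pool[k]), homolog=h + 1, parent=parent_tag)
            for h, k in enumerate(picks)
        ]
    return TrueGenome(functional_ploidy=ploidy, loci=genome)


def _reduced_half(copies: list[AlleleCopy], rng: np.random.Generator) -> list[int]:
    """Indices of a uniformly random half of the homolog set."""
    k = len(copies) // 2
    return sorted(rng.choice(len(copies), size=k, replace=False).tolist())


def form_male_gamete(
    sire: TrueGenome, rng: np.random.Generator
) -> dict[str, list[AlleleCopy]]:
    """Reduced sperm: half of the homologs at each locus, independently
    across loci (polysomic inheritance)."""
    if sire.functional_ploidy % 2:
        raise ValueError("sire ploidy must be even")
    gamete = {}
    for locus, copies in sire.loci.items():
        gamete[locus] = [copies[i] for i in _reduced_half(copies, rng)]
    return gamete


def form_female_gamete(
    dam: TrueGenome,
    model: GameteModel,
    r: float,
    rng: np.random.Generator,
) -> dict[str, list[AlleleCopy]]:
    """Oocyte under the chosen formation model (see module docstring).

    NORMAL gives ``dam_ploidy/2`` copies per locus; PB2_RETENTION and
    APOMIXIS_CLONE give ``dam_ploidy`` copies.
    """
    if dam.functional_ploidy % 2:
        raise ValueError("dam ploidy must be even")
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must be in [0, 1]")
    gamete: dict[str, list[AlleleCopy]] = {}
    for locus, copies in dam.loci.items():
        if model is GameteModel.APOMIXIS_CLONE:
            gamete[locus] = list(copies)
            continue
        selected = _reduced_half(copies, rng)
        reduced = [copies[i] for i in selected]
        if model is GameteModel.NORMAL:
            gamete[locus] = reduced
            continue
        # PB2 retention: duplicate the reduced set; each duplicate is
        # restored to a non-selected homolog's allele with probability r.
        non_selected = [copies[i] for i in range(len(copies)) if i not in selected]
        out = []
        for c in reduced:
            out.append(c)
            if rng.random() < r:
                donor = non_selected[int(rng.integers(len(non_selected)))]
                out.append(donor)
            else:
                out.append(c)
        gamete[locus] = out
    return gamete


def fertilize(
    oocyte: dict[str, list[AlleleCopy]],
    sperm: Sequence[dict[str, list[AlleleCopy]]],
) -> TrueGenome:
    """Concatenate gamete copy-lists into a zygote.

    The zygote's functional ploidy is the sum of the gamete ploidies and the
    parent-of-origin tags partition its copies exactly into the contributing
    gametes.
    """
    loci = set(oocyte)
    for s in sperm:
        if set(s) != loci:
            raise ValueError("gametes cover different locus sets")
    zygote: dict[str, list[AlleleCopy]] = {}
    for locus in oocyte:
        copies = list(oocyte[locus])
        for s in sperm:
            copies.extend(s[locus])
        zygote[locus] = copies
    ploidy = len(next(iter(zygote.values())))
    return TrueGenome(functional_ploidy=ploidy, loci=zygote)


def observe_genotype(
    genome: TrueGenome,
    dropout: float,
    rng: np.random.Generator,
) -> dict[str, LocusGenotype]:
    """Presence-only observation: distinct alleles among the copies, each
    independently dropped with probability ``dropout``.  A locus losing all
    alleles becomes missing (absent from the mapping)."""
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")
    observed = {}
    for locus in genome.loci:
        alleles = sorted(genome.distinct_alleles(locus))
        if dropout > 0.0:
            keep = rng.random(len(alleles)) >= dropout
            alleles = [a for a, k in zip(alleles, keep) if k]
        if alleles:
            observed[locus] = LocusGenotype(locus, frozenset(alleles))
    return observed


def mechanism_label(female_model: GameteModel, n_sperm: int) -> str:
    """Ground-truth mechanism name for a (female model, sperm count) arm."""
    if n_sperm == 2:
        return "DISPERMY" if female_model is GameteModel.NORMAL else (
            f"{female_model.value}+DISPERMY"
        )
    return female_model.value


def simulate_cross(config: CrossConfig) -> tuple[GenotypeTable, pd.DataFrame]:
    """Simulate the full cross; returns the genotype table and ground truth.

    The labels frame has columns ``sample``, ``true_mechanism``,
    ``true_ploidy``.  All randomness flows from one generator seeded with
    ``config.seed``; the same config yields identical output.  Parental
    genotypes are observed without dropout (they are the reference sets for
    the downstream analysis); offspring observations apply
    ``observation_dropout``.
    """
    rng = np.random.default_rng(config.seed)
    loci = config.locus_ids()
    pools = config.allele_pools()
    dam = simulate_parent(config.dam_ploidy, loci, pools, rng, "DAM")
    sire = simulate_parent(config.sire_ploidy, loci, pools, rng, "SIRE")

    individuals = [
        IndividualRecord("DAM", Role.DAM, observe_genotype(dam, 0.0, rng),
                         ploidy_label=config.dam_ploidy),
        IndividualRecord("SIRE", Role.SIRE, observe_genotype(sire, 0.0, rng),
                         ploidy_label=config.sire_ploidy),
    ]
    arms = [(GameteModel.NORMAL, 1)] * config.n_normal_offspring + [
        (config.female_model, config.n_sperm)
    ] * config.n_offspring
    labels = []
    for i, (model, n_sperm) in enumerate(arms):
        oocyte = form_female_gamete(dam, model, config.r, rng)
        sperm = [form_male_gamete(sire, rng) for _ in range(n_sperm)]
        zygote = fertilize(oocyte, sperm)
        sample_id = f"O{i + 1:03d}"
        individuals.append(
            IndividualRecord(
                sample_id,
                Role.OFFSPRING,
                observe_genotype(zygote, config.observation_dropout, rng),
                ploidy_label=zygote.functional_ploidy,
            )
        )
        labels.append(
            {
                "sample": sample_id,
                "true_mechanism": mechanism_label(model, n_sperm),
                "true_ploidy": zygote.functional_ploidy,
            }
        )
    return GenotypeTable(individuals), pd.DataFrame(
        labels, columns=["sample", "true_mechanism", "true_ploidy"]
    )


def simulate_dna_content(
    ploidy: int,
    per_set_pg: float,
    cv: float,
    n_nuclei: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-nucleus DNA contents: Gaussian around ``ploidy * per_set_pg``
    with relative spread ``cv`` (coefficient of variation of the stained
    nuclei population)."""
    if per_set_pg <= 0:
        raise ValueError("per_set_pg must be positive")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    mean = ploidy * per_set_pg
    if cv == 0:
        return np.full(n_nuclei, mean)
    return rng.normal(mean, cv * mean, size=n_nuclei)


def simulate_measurements(
    labels: pd.DataFrame,
    config: CrossConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-sample mean DNA content over ``config.n_nuclei`` simulated nuclei.

    Returns a frame with columns ``sample`` and ``dna_pg`` (the population
    mean a cytometer would report).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rows = []
    for row in labels.itertuples(index=False):
        sample = simulate_dna_content(
            int(row.true_ploidy), config.per_set_pg, config.dna_cv,
            config.n_nuclei, rng,
        )
        rows.append({"sample": row.sample, "dna_pg": float(np.mean(sample))})
    return pd.DataFrame(rows, columns=["sample", "dna_pg"])
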