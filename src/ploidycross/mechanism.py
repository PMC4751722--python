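"""Mechanism classification for spontaneous polyploids in a cross.

The classifier encodes the exclusion logic used to resolve how an
anomalous-ploidy offspring group arose, as a pure function of three pieces
of evidence:

1. *Ploidy arithmetic.*  The excess over the expected normal zygote ploidy
   is compared with the parental gamete ploidies.  An excess equal to the
   sire's gamete ploidy can only come from an extra sperm (polyspermy); an
   excess equal to the dam's full set count points to an unreduced oocyte.
   In the 4n × 6n cross the sperm are triploid, so dispermy yields 8n — a
   7n observation alone excludes polyspermy.

2. *Maternal genotype identity.*  Apomixis and premeiotic endomitosis
   produce clonal oocytes genetically identical to the dam; if offspring
   genotypes contain the dam's full allele set at (essentially) every
   locus, the clone route cannot be excluded and is preferred.

3. *Private-allele statistics.*  A significant increase in dam-private
   alleles over normally reduced siblings, with genotypes *not* identical
   to the dam (i.e. recombination occurred), is the signature of
   second-polar-body retention (second-division restitution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeTable, IndividualRecord, validate_cross_table
from .ploidy import PloidyCall, predict_zygote_ploidy
from .private_alleles import (
    Hypothesis,
    HypothesisOutcome,
    PrivateAlleleMatrix,
    count_private_alleles,
    test_hypotheses,
)
from .synthetic_cross import GameteModel

__all__ = [
    "Verdict",
    "MechanismVerdict",
    "PloidyExcess",
    "CrossClassification",
    "ploidy_excess",
    "maternal_identity_fraction",
    "infer_mechanism",
    "classify_cross",
]

log = logging.getLogger(__name__)


class Verdict(str, Enum):
    NORMAL = "NORMAL"
    MATERNAL_SDM_PB2 = "MATERNAL_SDM_PB2"
    MATERNAL_CLONE_APOMIXIS_OR_ENDOMITOSIS = "MATERNAL_CLONE_APOMIXIS_OR_ENDOMITOSIS"
    POLYSPERMY = "POLYSPERMY"
    UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class MechanismVerdict:
    """A verdict plus the ordered evidence trail that produced it.

    Each evidence entry is (criterion, outcome, detail).  The PB2 label
    follows the convention for recombination-bearing maternal duplication:
    the allele data demonstrate polar-body retention with recombination;
    meiosis II (second-division restitution) is the standard reading.
    """

    verdict: Verdict
    evidence: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("a verdict must carry at least one evidence entry")


@dataclass(frozen=True)
class PloidyExcess:
    """Observed functional ploidy relative to the normal-cross expectation."""

    observed_ploidy: int
    dam_ploidy: int
    sire_ploidy: int

    @property
    def expected_normal(self) -> int:
        return self.dam_ploidy // 2 + self.sire_ploidy // 2

    @property
    def excess(self) -> int:
        return self.observed_ploidy - self.expected_normal

    @property
    def dam_gamete_ploidy(self) -> int:
        return self.dam_ploidy // 2

    @property
    def sire_gamete_ploidy(self) -> int:
        return self.sire_ploidy // 2


def ploidy_excess(observed: int, dam_ploidy: int, sire_ploidy: int) -> PloidyExcess:
    """Excess of the observed ploidy over the normal zygote expectation
    (dam_ploidy/2 + sire_ploidy/2)."""
    if dam_ploidy % 2 or sire_ploidy % 2:
        raise ValueError("parental ploidies must be even")
    return PloidyExcess(observed, dam_ploidy, sire_ploidy)


def maternal_identity_fraction(
    offspring: IndividualRecord,
    dam: IndividualRecord,
    sire: IndividualRecord,
) -> float:
    """Fraction of loci at which the offspring could be a maternal clone.

    At each locus genotyped in the dam, the test is whether the offspring's
    observed alleles, after removing sire-only alleles, still contain the
    dam's *full* allele set — a conservative identity criterion under
    presence-only observation (a clonal oocyte transmits every dam allele).
    """
    loci = [l for l in dam.genotypes]
    if not loci:
        raise ValueError("no shared loci between dam and offspring")
    hits = 0
    for locus in loci:
        dam_set = dam.alleles_at(locus)
        sire_only = sire.alleles_at(locus) - dam_set
        if dam_set <= (offspring.alleles_at(locus) - sire_only):
            hits += 1
    return hits / len(loci)


def infer_mechanism(
    excess: PloidyExcess,
    identity_fraction: float | None,
    hyp: Sequence[HypothesisOutcome] | None,
    identity_threshold: float = 1.0,
) -> MechanismVerdict:
    """Apply the exclusion sequence to one anomalous ploidy group.

    Decision order: (1) zero excess is a normal zygote; (2) an excess equal
    to the sire's gamete ploidy (and distinguishable from the dam's) is
    polyspermy; (3) an excess equal to the dam's gamete contribution is
    maternal — a clone when offspring genotypes contain the dam's full set
    at ≥ ``identity_threshold`` of loci, otherwise PB2 retention when the
    dam-private increase (H1) is supported, otherwise unresolved; (4) when
    dam and sire gamete ploidies coincide the arithmetic is ambiguous and
    the genotype evidence (H1 vs H2) decides; any other excess is
    unresolved.
    """
    ev: list[tuple[str, str, str]] = []
    dam_g, sire_g = excess.dam_gamete_ploidy, excess.sire_gamete_ploidy
    ev.append((
        "ploidy_excess",
        str(excess.excess),
        f"observed {excess.observed_ploidy}n vs expected "
        f"{excess.expected_normal}n (dam gamete {dam_g}n, sire gamete {sire_g}n)",
    ))
    if excess.excess == 0:
        ev.append(("arithmetic", "normal", "no excess chromosome sets"))
        return MechanismVerdict(Verdict.NORMAL, tuple(ev))

    h1 = h2 = None
    if hyp:
        by = {h.hypothesis: h for h in hyp}
        h1 = by.get(Hypothesis.H1_DAM)
        h2 = by.get(Hypothesis.H2_SIRE)
        for h in (h1, h2):
            if h is not None:
                ev.append((
                    h.hypothesis.value,
                    "supported" if h.supported else "not supported",
                    f"t={h.evidence[0].t:.3g}, df={h.evidence[0].df}, "
                    f"p={h.evidence[0].p:.3g}, fold={h.fold:.3g}",
                ))
    if identity_fraction is not None:
        ev.append((
            "maternal_identity",
            f"{identity_fraction:.3g}",
            f"fraction of loci containing the dam's full allele set "
            f"(threshold {identity_threshold:g})",
        ))

    ambiguous = dam_g == sire_g
    if excess.excess == sire_g and not ambiguous and excess.excess != dam_g:
        ev.append((
            "arithmetic", "polyspermy",
            "excess equals the sire gamete ploidy and not the dam's full set",
        ))
        return MechanismVerdict(Verdict.POLYSPERMY, tuple(ev))

    if excess.excess == dam_g and not ambiguous:
        if identity_fraction is not None and identity_fraction >= identity_threshold:
            ev.append((
                "identity", "clone",
                "offspring genotypes indistinguishable from a clonal "
                "unreduced oocyte (apomixis or premeiotic endomitosis)",
            ))
            return MechanismVerdict(
                Verdict.MATERNAL_CLONE_APOMIXIS_OR_ENDOMITOSIS, tuple(ev)
            )
        if h1 is not None and h1.supported:
            ev.append((
                "conclusion", "pb2_retention",
                "dam-private alleles increased and genotypes are not clonal: "
                "polar-body retention (recombination-bearing maternal "
                "duplication, meiosis II)",
            ))
            return MechanismVerdict(Verdict.MATERNAL_SDM_PB2, tuple(ev))
        ev.append((
            "conclusion", "unresolved",
            "maternal excess but neither clonal identity nor a supported "
            "dam-private increase",
        ))
        return MechanismVerdict(Verdict.UNRESOLVED, tuple(ev))

    if ambiguous and excess.excess == dam_g:
        # dam and sire gamete ploidies coincide: arithmetic cannot assign
        # the parent; fall back to genotype evidence.
        if identity_fraction is not None and identity_fraction >= identity_threshold:
            return MechanismVerdict(
                Verdict.MATERNAL_CLONE_APOMIXIS_OR_ENDOMITOSIS,
                tuple(ev + [("identity", "clone", "clonal maternal genotypes")]),
            )
        h1_ok = bool(h1 and h1.supported)
        h2_ok = bool(h2 and h2.supported)
        if h1_ok and not h2_ok:
            return MechanismVerdict(
                Verdict.MATERNAL_SDM_PB2,
                tuple(ev + [("conclusion", "pb2_retention",
                             "genotype evidence assigns the excess to the dam")]),
            )
        if h2_ok and not h1_ok:
            return MechanismVerdict(
                Verdict.POLYSPERMY,
                tuple(ev + [("conclusion", "polyspermy",
                             "genotype evidence assigns the excess to the sire")]),
            )
        return MechanismVerdict(
            Verdict.UNRESOLVED,
            tuple(ev + [("conclusion", "unresolved",
                         "equal gamete ploidies and inconclusive genotypes")]),
        )

    ev.append((
        "arithmetic", "unresolved",
        "excess matches neither parental gamete contribution",
    ))
    return MechanismVerdict(Verdict.UNRESOLVED, tuple(ev))


@dataclass
class CrossClassification:
    """Output of :func:`classify_cross`."""

    verdicts: dict[str, MechanismVerdict]  # per offspring sample id
    group_verdicts: dict[int, MechanismVerdict]  # per anomalous called ploidy
    matrix: PrivateAlleleMatrix | None
    hypotheses: list[HypothesisOutcome] | None
    summary: str

    def verdict_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.verdicts.values():
            out[v.verdict.value] = out.get(v.verdict.value, 0) + 1
        return out


def classify_cross(
    table: GenotypeTable,
    ploidy_calls: Sequence[PloidyCall],
    dam_ploidy: int = 4,
    sire_ploidy: int = 6,
    alpha: float = 0.05,
    identity_threshold: float = 1.0,
    subsample_seed: int = 0,
) -> CrossClassification:
    """Run the full inference chain on one cross.

    Offspring are grouped by called functional ploidy; the group at the
    normal expectation (dam/2 + sire/2) is the baseline.  For each
    anomalous group, the private-allele battery is run against an
    equal-size subsample of the baseline (seeded, deterministic — mirrors
    comparing the anomalous fish with randomly chosen normal full sibs),
    the mean maternal-identity fraction is computed, and the exclusion
    sequence yields a group verdict inherited by its members.

    Deterministic given inputs: no step draws randomness beyond the seeded
    baseline subsample.
    """
    report = validate_cross_table(table)
    calls_by_sample = {c.sample_id: c for c in ploidy_calls}
    offspring_ids = [o.sample_id for o in table.offspring]
    missing = [s for s in offspring_ids if s not in calls_by_sample]
    if missing:
        raise ValueError(f"offspring without ploidy calls: {missing}")

    expected = predict_zygote_ploidy(dam_ploidy, sire_ploidy, GameteModel.NORMAL, 1)
    groups_by_ploidy: dict[int | None, list[str]] = {}
    for s in offspring_ids:
        groups_by_ploidy.setdefault(calls_by_sample[s].called_ploidy, []).append(s)

    baseline = groups_by_ploidy.get(expected, [])
    anomalous = {
        p: members for p, members in groups_by_ploidy.items()
        if p is not None and p != expected
    }

    verdicts: dict[str, MechanismVerdict] = {}
    group_verdicts: dict[int, MechanismVerdict] = {}
    matrix = None
    hypotheses = None
    for s in groups_by_ploidy.get(None, []):
        verdicts[s] = MechanismVerdict(
            Verdict.UNRESOLVED,
            (("ploidy_call", "no-call", "DNA content outside every candidate band"),),
        )
    for s in baseline:
        verdicts[s] = MechanismVerdict(
            Verdict.NORMAL,
            (("ploidy_excess", "0", f"called {expected}n as expected"),),
        )

    for obs_ploidy in sorted(anomalous):
        members = anomalous[obs_ploidy]
        excess = ploidy_excess(obs_ploidy, dam_ploidy, sire_ploidy)
        identity = float(np.mean([
            maternal_identity_fraction(table.individual(s), table.dam, table.sire)
            for s in members
        ]))
        hyp = None
        if baseline:
            rng = np.random.default_rng(subsample_seed)
            if len(baseline) > len(members):
                matched = sorted(
                    rng.choice(baseline, size=len(members), replace=False).tolist()
                )
            else:
                matched = list(baseline)
                if len(baseline) < len(members):
                    log.warning(
                        "baseline group smaller than anomalous group "
                        "(%d < %d): fold change not size-matched",
                        len(baseline), len(members),
                    )
            matrix = count_private_alleles(
                table,
                {f"{expected}n": matched, f"{obs_ploidy}n": members},
            )
            hyp = test_hypotheses(
                matrix,
                alpha=alpha,
                baseline=f"{expected}n",
                elevated=f"{obs_ploidy}n",
                exclude_loci=report.uninformative_loci,
            )
            hypotheses = hyp
        group_verdict = infer_mechanism(excess, identity, hyp, identity_threshold)
        group_verdicts[obs_ploidy] = group_verdict
        for s in members:
            verdicts[s] = group_verdict

    if not anomalous:
        summary = "no spontaneous polyploids detected"
    else:
        parts = [
            f"{len(anomalous[p])} offspring at {p}n -> {group_verdicts[p].verdict.value}"
            for p in sorted(anomalous)
        ]
        summary = "; ".join(parts)
    return CrossClassification(
        verdicts=verdicts,
        group_verdicts=group_verdicts,
        matrix=matrix,
        hypotheses=hypotheses,
        summary=summary,
    )
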