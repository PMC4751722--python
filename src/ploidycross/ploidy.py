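"""Ploidy calling from DNA content and ploidy arithmetic for crosses.

Functional ploidy (the re-diploidised 2n–4n–6n sturgeon scale) is called by
comparing a per-nucleus DNA content (pg, flow cytometry or Feulgen
densitometry) or a ratio to a diploid standard against candidate multiples
of a per-functional-set reference.  The measured contents of the study's
sibling groups (8.98 pg at 5n, 15.02 pg at 7n) imply *different* per-set
constants (1.796 vs 2.146 pg), so the reference is always an explicit
input — either one scalar or a per-candidate mapping — and calls outside a
relative tolerance band become no-calls rather than forced assignments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .synthetic_cross import GameteModel

__all__ = [
    "PloidyCall",
    "DensitometryStandards",
    "TENCH_STANDARDS",
    "PENTAPLOID_PG_PER_SET",
    "HEPTAPLOID_PG_PER_SET",
    "call_ploidy",
    "call_ploidy_batch",
    "estimate_genome_size",
    "predict_zygote_ploidy",
    "predict_chromosome_number",
]

log = logging.getLogger(__name__)

# Per-functional-set contents implied by the two measured sibling groups.
PENTAPLOID_PG_PER_SET = 8.98 / 5  # 1.796
HEPTAPLOID_PG_PER_SET = 15.02 / 7  # ~2.146


@dataclass(frozen=True)
class PloidyCall:
    """A per-sample ploidy call.

    ``called_ploidy`` is None for a no-call (residual beyond tolerance).
    ``margin`` is the gap between the best and second-best absolute
    residuals, in measurement units; larger means a safer call.
    """

    sample_id: str
    called_ploidy: int | None
    residual: float
    margin: float
    content_pg: float | None = None
    ratio_to_standard: float | None = None


@dataclass(frozen=True)
class DensitometryStandards:
    """Feulgen densitometry standards: (label, mean IOD, known pg) triples."""

    standards: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if not self.standards:
            raise ValueError("need at least one standard")
        for label, iod, pg in self.standards:
            if iod <= 0 or pg <= 0:
                raise ValueError(f"standard {label!r}: IOD and pg must be positive")


def tench_standards(iod_2n: float, iod_3n: float) -> DensitometryStandards:
    """Diploid and induced-triploid tench internal standards
    (2.02 and 3.10 pg per nucleus) at the measured IODs."""
    return DensitometryStandards(
        (("2n tench", iod_2n, 2.02), ("3n tench", iod_3n, 3.10))
    )


TENCH_STANDARDS = (("2n tench", 2.02), ("3n tench", 3.10))  # (label, pg)


def _reference_for(candidate: int, reference: float | Mapping[int, float]) -> float:
    if isinstance(reference, Mapping):
        try:
            ref = reference[candidate]
        except KeyError:
            raise ValueError(f"no per-set reference for candidate {candidate}") from None
    else:
        ref = reference
    if ref <= 0:
        raise ValueError("per-set reference must be positive")
    return float(ref)


def call_ploidy(
    measurement: float,
    per_set_reference: float | Mapping[int, float],
    candidates: Iterable[int],
    tolerance: float = 0.15,
    sample_id: str = "",
) -> PloidyCall:
    """Nearest-candidate ploidy call with a relative no-call band.

    The call is the candidate minimising ``|measurement - candidate * ref|``
    (``ref`` per-candidate when a mapping is given).  If the winning relative
    residual ``|measurement - c*ref| / (c*ref)`` exceeds ``tolerance`` the
    sample is a no-call.  Ties break toward the lower ploidy with a logged
    warning.  The call is invariant to rescaling measurement and reference
    by the same positive constant.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if measurement <= 0:
        raise ValueError("measurement must be positive")
    residuals = []
    for c in candidates:
        expected = c * _reference_for(c, per_set_reference)
        residuals.append((abs(measurement - expected), expected, c))
    residuals.sort(key=lambda t: (t[0], t[2]))  # tie -> lower ploidy
    best_abs, best_expected, best = residuals[0]
    if len(residuals) > 1 and residuals[1][0] == best_abs:
        log.warning(
            "sample %s: tie between ploidy %d and %d, calling %d",
            sample_id, best, residuals[1][2], best,
        )
    margin = residuals[1][0] - best_abs if len(residuals) > 1 else math.inf
    rel = best_abs / best_expected
    called = best if rel <= tolerance else None
    return PloidyCall(
        sample_id=sample_id,
        called_ploidy=called,
        residual=rel,
        margin=margin,
        content_pg=measurement,
    )


def call_ploidy_batch(
    measurements: pd.DataFrame,
    per_set_reference: float | Mapping[int, float],
    candidates: Iterable[int],
    tolerance: float = 0.15,
) -> tuple[list[PloidyCall], pd.DataFrame]:
    """Call every sample in a measurement frame and summarise.

    ``measurements`` needs columns ``sample`` and one of ``dna_pg`` /
    ``ratio_to_standard``.  Returns the per-sample calls and a frequency
    table with columns ``ploidy`` (``"no-call"`` for rejections) and
    ``count``.
    """
    value_col = "dna_pg" if "dna_pg" in measurements.columns else "ratio_to_standard"
    calls = []
    for row in measurements.itertuples(index=False):
        call = call_ploidy(
            float(getattr(row, value_col)),
            per_set_reference,
            candidates,
            tolerance,
            sample_id=str(row.sample),
        )
        if value_col == "ratio_to_standard":
            call = PloidyCall(
                call.sample_id, call.called_ploidy, call.residual, call.margin,
                content_pg=None, ratio_to_standard=float(getattr(row, value_col)),
            )
        calls.append(call)
    counts: dict[str, int] = {}
    for call in calls:
        key = f"{call.called_ploidy}n" if call.called_ploidy else "no-call"
        counts[key] = counts.get(key, 0) + 1
    summary = pd.DataFrame(
        sorted(counts.items()), columns=["ploidy", "count"]
    )
    return calls, summary


def estimate_genome_size(
    sample_iod: float, standards: DensitometryStandards
) -> float:
    """Genome size in pg from Feulgen IOD against known standards.

    Each standard implies ``(sample_iod / standard_iod) * standard_pg``; the
    estimate is the mean over standards (linear in ``sample_iod``).
    """
    if sample_iod <= 0:
        raise ValueError("sample IOD must be positive")
    implied = [
        (sample_iod / iod) * pg for _, iod, pg in standards.standards
    ]
    return sum(implied) / len(implied)


def _gamete_sets(
    dam_ploidy: int, sire_ploidy: int, female_model: GameteModel, n_sperm: int
) -> tuple[int, int]:
    if dam_ploidy % 2 or sire_ploidy % 2:
        raise ValueError("parental ploidies must be even")
    if n_sperm not in (1, 2):
        raise ValueError("n_sperm must be 1 or 2")
    if isinstance(female_model, str):
        female_model = GameteModel(female_model)
    oocyte = (
        dam_ploidy // 2 if female_model is GameteModel.NORMAL else dam_ploidy
    )
    return oocyte, n_sperm * (sire_ploidy // 2)


def predict_zygote_ploidy(
    dam_ploidy: int,
    sire_ploidy: int,
    female_model: GameteModel = GameteModel.NORMAL,
    n_sperm: int = 1,
) -> int:
    """Expected functional zygote ploidy for a cross/mechanism combination.

    The oocyte contributes half the dam's sets (normal meiosis) or all of
    them (second-polar-body retention or a clonal unreduced oocyte); each
    sperm contributes half the sire's sets.  For the 4n × 6n cross this
    gives 2+3=5 (normal), 4+3=7 (PB2 retention) and 2+3+3=8 (dispermy).
    """
    oocyte, sperm = _gamete_sets(dam_ploidy, sire_ploidy, female_model, n_sperm)
    return oocyte + sperm


def predict_chromosome_number(
    dam_count: int,
    sire_count: int,
    female_model: GameteModel = GameteModel.NORMAL,
    n_sperm: int = 1,
) -> int:
    """Expected zygote chromosome count, same arithmetic on somatic counts.

    Halves round half-up because the parental counts are themselves
    approximate (e.g. ~245 and ~368 for the 4n and 6n parents).
    """
    if dam_count <= 0 or sire_count <= 0:
        raise ValueError("chromosome counts must be positive")
    if isinstance(female_model, str):
        female_model = GameteModel(female_model)
    half = lambda x: math.floor(x / 2 + 0.5)
    oocyte = half(dam_count) if female_model is GameteModel.NORMAL else dam_count
    if n_sperm not in (1, 2):
        raise ValueError("n_sperm must be 1 or 2")
    return oocyte + n_sperm * half(sire_count)
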