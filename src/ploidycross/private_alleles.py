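"""Private-allele coding and the parental-origin hypothesis battery.

A *private allele* is present in exactly one of the two parents.  Because
polyploid microsatellite genotypes are presence-only, each distinct private
allele observed in an offspring scores 1 regardless of dosage.  The per-locus
counts, summed within a ploidy group, form the evidence for where a
duplicated chromosome set came from: an elevated group carrying more
dam-private alleles than its normally reduced full siblings points to a
maternal origin, more sire-private alleles to a paternal one.

The significance of the increase is assessed with a paired Student t test
over loci (one pair of group counts per locus), preceded by a Shapiro–Wilk
check of the paired differences.  Sign convention: differences are
baseline − elevated, so a genuine increase in the elevated group yields a
*negative* t — an increase is supported when p < alpha and mean_diff < 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeTable
from .synthetic_cross import CrossConfig, GameteModel, simulate_cross

__all__ = [
    "AlleleClass",
    "Hypothesis",
    "PrivateAlleleMatrix",
    "PairedTestResult",
    "HypothesisOutcome",
    "CalibrationResult",
    "classify_allele",
    "count_private_alleles",
    "paired_t",
    "shapiro_wilk_check",
    "fold_change",
    "test_hypotheses",
    "calibrate_r",
    "read_count_matrix",
    "write_count_matrix",
]

log = logging.getLogger(__name__)


class AlleleClass(str, Enum):
    DAM_PRIVATE = "DAM_PRIVATE"
    SIRE_PRIVATE = "SIRE_PRIVATE"
    SHARED = "SHARED"
    NON_PARENTAL = "NON_PARENTAL"


class Hypothesis(str, Enum):
    H1_DAM = "H1_DAM"  # duplicated sets of maternal origin
    H2_SIRE = "H2_SIRE"  # duplicated sets of paternal origin
    H3_BOTH = "H3_BOTH"  # duplication from both parents


def classify_allele(
    allele: int, dam_set: frozenset[int] | set[int], sire_set: frozenset[int] | set[int]
) -> AlleleClass:
    """Classify one allele against the two parental sets (exhaustive and
    mutually exclusive)."""
    if not dam_set or not sire_set:
        raise ValueError("parental allele sets must be non-empty")
    in_dam, in_sire = allele in dam_set, allele in sire_set
    if in_dam and in_sire:
        return AlleleClass.SHARED
    if in_dam:
        return AlleleClass.DAM_PRIVATE
    if in_sire:
        return AlleleClass.SIRE_PRIVATE
    return AlleleClass.NON_PARENTAL


@dataclass
class PrivateAlleleMatrix:
    """Per-locus × per-group private-allele counts.

    ``counts`` is a long frame with columns ``locus``, ``group``, ``parent``
    (``DAM``/``SIRE``) and ``count`` — the sum over the group's members of
    the number of distinct parent-private alleles each observes at the
    locus.  ``groups`` maps group label to member sample ids (may be empty
    for counts-only data read from file).
    """

    loci: list[str]
    groups: dict[str, list[str]]
    counts: pd.DataFrame

    def per_locus(self, group: str, parent: str) -> pd.Series:
        """Counts for one (group, parent) as a Series indexed by locus,
        in ``self.loci`` order (missing cells are 0)."""
        sub = self.counts[
            (self.counts["group"] == group) & (self.counts["parent"] == parent)
        ]
        s = sub.set_index("locus")["count"]
        return s.reindex(self.loci, fill_value=0).astype(int)

    def total(self, group: str, parent: str) -> int:
        return int(self.per_locus(group, parent).sum())


def count_private_alleles(
    table: GenotypeTable, groups: Mapping[str, Sequence[str]]
) -> PrivateAlleleMatrix:
    """Count distinct private alleles per offspring, summed within groups.

    SHARED alleles are uninformative and NON_PARENTAL alleles (mutation or
    scoring artefact) are excluded from all counts; non-parental hits are
    logged.  A missing genotype contributes zero.
    """
    known = {ind.sample_id for ind in table.individuals}
    for label, members in groups.items():
        unknown = [m for m in members if m not in known]
        if unknown:
            raise KeyError(f"group {label!r}: unknown samples {unknown}")
    dam, sire = table.dam, table.sire
    rows = []
    n_non_parental = 0
    for locus in table.loci:
        dam_set, sire_set = dam.alleles_at(locus), sire.alleles_at(locus)
        for label, members in groups.items():
            n_dam = n_sire = 0
            for member in members:
                for allele in table.individual(member).alleles_at(locus):
                    cls = classify_allele(allele, dam_set, sire_set)
                    if cls is AlleleClass.DAM_PRIVATE:
                        n_dam += 1
                    elif cls is AlleleClass.SIRE_PRIVATE:
                        n_sire += 1
                    elif cls is AlleleClass.NON_PARENTAL:
                        n_non_parental += 1
            rows.append({"locus": locus, "group": label, "parent": "DAM", "count": n_dam})
            rows.append({"locus": locus, "group": label, "parent": "SIRE", "count": n_sire})
    if n_non_parental:
        log.warning("excluded %d non-parental allele observations", n_non_parental)
    sizes = {len(m) for m in groups.values()}
    if len(sizes) > 1:
        log.warning("unequal group sizes %s: fold changes are not size-matched",
                    {k: len(v) for k, v in groups.items()})
    return PrivateAlleleMatrix(
        loci=list(table.loci),
        groups={k: list(v) for k, v in groups.items()},
        counts=pd.DataFrame(rows, columns=["locus", "group", "parent", "count"]),
    )


@dataclass(frozen=True)
class PairedTestResult:
    """Paired Student t test on per-locus differences d = y − x."""

    t: float
    df: int
    p: float
    mean_diff: float
    normality_p: float | None = None
    degenerate: bool = False


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Paired t test with d = y − x, two-sided p from the t distribution.

    Degenerate cases are defined rather than NaN: all-zero differences give
    t = 0, p = 1; zero variance with nonzero mean gives t = ±inf, p = 0,
    flagged ``degenerate``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    normality_p = shapiro_wilk_check(d)
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, df, 1.0, 0.0, normality_p, False)
        t = math.copysign(math.inf, mean)
        return PairedTestResult(t, df, 0.0, mean, normality_p, True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PairedTestResult(t, df, p, mean, normality_p, False)


def shapiro_wilk_check(d: Sequence[float]) -> float | None:
    """Shapiro–Wilk p-value for the paired differences; advisory only.

    Returns None when not computable (n < 3 or constant input).
    """
    d = np.asarray(d, dtype=float)
    if d.size < 3 or np.ptp(d) == 0.0:
        return None
    return float(stats.shapiro(d).pvalue)


def fold_change(
    matrix: PrivateAlleleMatrix,
    parent: str,
    group_num: str,
    group_den: str,
) -> float:
    """Ratio of group totals (summed over loci) for one parent's private
    alleles; ``parent`` is ``"DAM"``, ``"SIRE"`` or ``"BOTH"``.  NaN when
    the denominator total is zero (undefined)."""
    parents = ("DAM", "SIRE") if parent == "BOTH" else (parent,)
    num = sum(matrix.total(group_num, p) for p in parents)
    den = sum(matrix.total(group_den, p) for p in parents)
    if den == 0:
        log.warning("fold change undefined: zero %s total in group %r", parent, group_den)
        return math.nan
    return num / den


@dataclass(frozen=True)
class HypothesisOutcome:
    """Verdict on one origin hypothesis with its evidence trail."""

    hypothesis: Hypothesis
    supported: bool
    evidence: tuple[PairedTestResult, ...]
    fold: float


def test_hypotheses(
    matrix: PrivateAlleleMatrix,
    alpha: float = 0.05,
    baseline: str | None = None,
    elevated: str | None = None,
    exclude_loci: Iterable[str] = (),
) -> list[HypothesisOutcome]:
    """Run the three-hypothesis battery on a two-group matrix.

    ``baseline`` is the normally reduced sibling group and ``elevated`` the
    anomalous-ploidy group; when omitted they default to the two group
    labels in sorted order (e.g. "5n" baseline, "7n" elevated).  Loci in
    ``exclude_loci`` (typically flagged uninformative) are dropped before
    testing, reducing the degrees of freedom.

    An increase is supported when the paired t (d = baseline − elevated) is
    significant at ``alpha`` with mean_diff < 0.  H3 holds iff H1 and H2
    both hold.
    """
    labels = sorted(matrix.groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, have {labels}")
    if baseline is None or elevated is None:
        baseline, elevated = labels
    if {baseline, elevated} != set(labels):
        raise ValueError("baseline/elevated must name the matrix's two groups")
    loci = [l for l in matrix.loci if l not in set(exclude_loci)]
    dropped = [l for l in matrix.loci if l in set(exclude_loci)]
    if dropped:
        log.info("excluding uninformative loci from the battery: %s", dropped)
    if len(loci) < 2:
        raise ValueError("fewer than 2 informative loci: paired t not defined")
    sub = replace_loci(matrix, loci)

    def one_parent(parent: str) -> tuple[PairedTestResult, float]:
        test = paired_t(
            sub.per_locus(elevated, parent).to_numpy(),
            sub.per_locus(baseline, parent).to_numpy(),
        )
        return test, fold_change(sub, parent, elevated, baseline)

    dam_test, dam_fold = one_parent("DAM")
    sire_test, sire_fold = one_parent("SIRE")
    h1 = dam_test.p < alpha and dam_test.mean_diff < 0
    h2 = sire_test.p < alpha and sire_test.mean_diff < 0
    return [
        HypothesisOutcome(Hypothesis.H1_DAM, h1, (dam_test,), dam_fold),
        HypothesisOutcome(Hypothesis.H2_SIRE, h2, (sire_test,), sire_fold),
        HypothesisOutcome(
            Hypothesis.H3_BOTH, h1 and h2, (dam_test, sire_test),
            fold_change(sub, "BOTH", elevated, baseline),
        ),
    ]


def replace_loci(matrix: PrivateAlleleMatrix, loci: Sequence[str]) -> PrivateAlleleMatrix:
    """A view of the matrix restricted to ``loci`` (order preserved)."""
    keep = set(loci)
    return PrivateAlleleMatrix(
        loci=list(loci),
        groups=dict(matrix.groups),
        counts=matrix.counts[matrix.counts["locus"].isin(keep)].reset_index(drop=True),
    )


@dataclass
class CalibrationResult:
    """Grid inversion of the simulator's fold-change curve."""

    r_hat: float
    curve: pd.DataFrame  # columns r, fold
    boundary: bool


def calibrate_r(
    target_fold: float,
    config: CrossConfig,
    grid: Sequence[float] = tuple(np.linspace(0.0, 1.0, 11)),
    n_offspring: int = 500,
) -> CalibrationResult:
    """Find the heterozygosity-restoration probability r whose simulated
    expected dam-private fold change best matches ``target_fold``.

    For each grid r, a cross with ``n_offspring`` PB2-retention offspring
    and as many normally reduced siblings is simulated from the same seed
    (common random base), and the dam-private fold (PB2 group over normal
    group) recorded.  ``boundary`` flags a target outside the achievable
    curve range.
    """
    folds = []
    for r in grid:
        cfg = replace(
            config,
            r=float(r),
            female_model=GameteModel.PB2_RETENTION,
            n_sperm=1,
            n_offspring=n_offspring,
            n_normal_offspring=n_offspring,
        )
        table, labels = simulate_cross(cfg)
        normal = labels[labels["true_mechanism"] == "NORMAL"]["sample"].tolist()
        pb2 = labels[labels["true_mechanism"] == "PB2_RETENTION"]["sample"].tolist()
        matrix = count_private_alleles(table, {"normal": normal, "pb2": pb2})
        folds.append(fold_change(matrix, "DAM", "pb2", "normal"))
    curve = pd.DataFrame({"r": list(grid), "fold": folds})
    idx = int(np.argmin(np.abs(curve["fold"] - target_fold)))
    boundary = bool(
        target_fold < curve["fold"].min() or target_fold > curve["fold"].max()
    )
    return CalibrationResult(float(curve["r"][idx]), curve, boundary)


_MATRIX_COLUMNS = ["locus", "group", "parent", "count"]


def read_count_matrix(path: str | Path) -> PrivateAlleleMatrix:
    """Read a per-locus count matrix TSV (columns locus, group, parent,
    count) — the layout of a supplementary private-allele table, enabling
    the full battery without raw genotypes."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _MATRIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: empty count matrix")
    df = df[_MATRIX_COLUMNS].copy()
    df["count"] = df["count"].astype(int)
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    bad = set(df["parent"]) - {"DAM", "SIRE"}
    if bad:
        raise ValueError(f"{path}: parent must be DAM or SIRE, found {sorted(bad)}")
    loci = list(dict.fromkeys(df["locus"]))
    groups = {g: [] for g in dict.fromkeys(df["group"])}
    return PrivateAlleleMatrix(loci=loci, groups=groups, counts=df)


def write_count_matrix(matrix: PrivateAlleleMatrix, path: str | Path) -> None:
    """Write the count matrix as TSV (row order as constructed, which is
    deterministic; read∘write is the identity)."""
    matrix.counts.to_csv(path, sep="\t", index=False)
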