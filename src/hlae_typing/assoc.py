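"""Case-control association statistics for a biallelic SNP.

Implements the analysis pipeline for a case-control SNP study: allele and
genotype frequencies, a 1-df chi-square Hardy-Weinberg goodness-of-fit test
per cohort, uncorrected Pearson chi-square on 2x2 tables, two-sided Fisher's
exact test for sparse tables, and odds ratios with Woolf (logit) 95%
confidence intervals. ``association_report`` assembles these into the full
three-table report (allele-level case vs control, per-subtype allele tables,
and per-genotype tables) with a ``summary()`` in the style of a fitted-model
results object.

Conventions, fixed deliberately:

* Pearson chi-square is uncorrected (no Yates continuity correction) by
  default; the corrected variant is available behind a flag.
* Fisher's two-sided p sums hypergeometric point probabilities <= that of
  the observed table (the standard two-sided rule).
* The Woolf CI is exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)); with a
  zero cell the CI (and OR for a zero off-diagonal product) is undefined and
  an error is raised rather than silently continuity-corrected.
* Per-genotype tests are "this genotype vs all others"; Fisher replaces
  chi-square whenever any expected cell is below 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, StatisticError
from .genotype import GENOTYPES, GG, GT, TT

CHI2 = "CHI2"
FISHER = "FISHER"

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts (G/G, G/T, T/T) of one cohort."""

    label: str
    n_GG: int
    n_GT: int
    n_TT: int

    def __post_init__(self) -> None:
        if min(self.n_GG, self.n_GT, self.n_TT) < 0:
            raise InputError(f"cohort {self.label!r}: negative genotype count")

    @property
    def size(self) -> int:
        return self.n_GG + self.n_GT + self.n_TT

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_GG, self.n_GT, self.n_TT)


@dataclass(frozen=True)
class AlleleCounts:
    """Allele (chromosome) counts of one cohort: 2n chromosomes in total."""

    label: str
    n_G: int
    n_T: int

    def __post_init__(self) -> None:
        if min(self.n_G, self.n_T) < 0:
            raise InputError(f"cohort {self.label!r}: negative allele count")

    @property
    def total(self) -> int:
        return self.n_G + self.n_T


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts; rows are cohorts, columns are outcome classes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("negative cell count in 2x2 table")
        if self.a + self.b + self.c + self.d == 0:
            raise InputError("empty 2x2 table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssocResult:
    """Test outcome for one 2x2 comparison."""

    chi2: float | None
    p: float
    or_: float | None
    ci_low: float | None
    ci_high: float | None
    method: str


@dataclass(frozen=True)
class HWEResult:
    """1-df chi-square Hardy-Weinberg goodness-of-fit outcome for one cohort."""

    chi2: float
    p: float
    expected: tuple[float, float, float]


def allele_counts(gc: GenotypeCounts) -> AlleleCounts:
    """Chromosome counts implied by genotype counts: conserves 2n."""
    return AlleleCounts(
        label=gc.label,
        n_G=2 * gc.n_GG + gc.n_GT,
        n_T=2 * gc.n_TT + gc.n_GT,
    )


def frequencies(counts: Sequence[float]) -> np.ndarray:
    """Counts normalized to proportions; rejects an all-zero vector."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise StatisticError("cannot compute frequencies of an empty cohort")
    return arr / total


def pearson_chi2(
    t: ContingencyTable2x2, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table with its 1-df upper-tail p.

    Uncorrected by default: chi2 = N(ad-bc)^2 / [(a+b)(c+d)(a+c)(b+d)].
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        raise StatisticError("chi-square undefined: zero margin in 2x2 table")
    num = abs(a * d - b * c)
    if continuity_correction:
        num = max(num - t.n / 2, 0.0)
    chi2 = t.n * num**2 / np.prod(margins, dtype=float)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def fisher_exact(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (hypergeometric point-probability rule)."""
    if 0 in ((t.a + t.b), (t.c + t.d), (t.a + t.c), (t.b + t.d)):
        return 1.0
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def odds_ratio(t: ContingencyTable2x2) -> tuple[float, float, float]:
    """Cross-product odds ratio ad/bc with the Woolf (logit) 95% CI."""
    if t.b * t.c == 0:
        raise StatisticError("odds ratio undefined: zero off-diagonal product")
    if 0 in (t.a, t.d):
        raise StatisticError("Woolf CI undefined: zero cell in 2x2 table")
    or_ = (t.a * t.d) / (t.b * t.c)
    se = np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    lo = float(np.exp(np.log(or_) - _Z95 * se))
    hi = float(np.exp(np.log(or_) + _Z95 * se))
    return float(or_), lo, hi


def hwe_test(gc: GenotypeCounts) -> HWEResult:
    """Hardy-Weinberg 1-df chi-square goodness of fit on one cohort.

    Expected genotype counts are (p^2 n, 2pq n, q^2 n) with p, q the observed
    allele frequencies. A monomorphic cohort fits trivially (chi2 = 0, p = 1).
    """
    n = gc.size
    if n == 0:
        raise StatisticError(f"cohort {gc.label!r} is empty")
    ac = allele_counts(gc)
    p_hat, q_hat = frequencies([ac.n_G, ac.n_T])
    expected = (p_hat**2 * n, 2 * p_hat * q_hat * n, q_hat**2 * n)
    if q_hat == 0 or p_hat == 0:
        return HWEResult(chi2=0.0, p=1.0, expected=expected)
    observed = gc.as_tuple()
    chi2 = float(sum((o - e) ** 2 / e for o, e in zip(observed, expected)))
    return HWEResult(chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)), expected=expected)


def _expected_cells(t: ContingencyTable2x2) -> np.ndarray:
    arr = t.as_array()
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()


def compare_2x2(t: ContingencyTable2x2, force_fisher: bool = False) -> AssocResult:
    """Chi-square comparison with Fisher fallback for sparse tables.

    Fisher's exact test replaces the chi-square whenever any expected cell is
    below 5 (or on request). OR and CI are attached when defined, else None.
    """
    use_fisher = force_fisher or bool((_expected_cells(t) < 5).any())
    if use_fisher:
        chi2, p, method = None, fisher_exact(t), FISHER
    else:
        chi2, p = pearson_chi2(t)
        method = CHI2
    try:
        or_, lo, hi = odds_ratio(t)
    except StatisticError:
        or_, lo, hi = None, None, None
    return AssocResult(chi2=chi2, p=p, or_=or_, ci_low=lo, ci_high=hi, method=method)


# ---------------------------------------------------------------------------
# Full study report


@dataclass
class AssociationReport:
    """Results object holding the three study tables plus per-cohort HWE.

    ``allele_table`` compares case vs control chromosome counts;
    ``subtype_table`` compares each case subtype's alleles against controls;
    ``genotype_table`` tests each genotype against all others. ``notes``
    records internal inconsistencies detected in the inputs (e.g. printed
    allele counts that disagree with genotype-derived ones).
    """

    allele_table: pd.DataFrame
    subtype_table: pd.DataFrame
    genotype_table: pd.DataFrame
    hwe: dict[str, HWEResult]
    notes: list[str] = field(default_factory=list)

    def summary(self, digits: int = 3) -> str:
        """Plain-text report mirroring the three-table study layout."""
        fmt = {
            c: (lambda v: "" if pd.isna(v) else f"{v:.2f}")
            for c in ("freq_pct", "case_pct", "control_pct")
        }
        lines = ["Case-control association report", "=" * 60]
        for title, df in (
            ("Allele-level comparison", self.allele_table),
            ("Subtype allele comparisons", self.subtype_table),
            ("Genotype-level comparisons (each vs rest)", self.genotype_table),
        ):
            if df.empty:
                continue
            lines += [
                "",
                title,
                "-" * len(title),
                df.to_string(
                    index=False,
                    float_format=lambda v: f"{v:.{digits}f}",
                    formatters=fmt,
                    na_rep="-",
                ),
            ]
        lines += ["", "Hardy-Weinberg equilibrium (1-df chi-square)", "-" * 44]
        for label, res in self.hwe.items():
            verdict = "accepted" if res.p > 0.05 else "REJECTED"
            lines.append(
                f"{label}: chi2 = {res.chi2:.{digits}f}, p = {res.p:.{digits}f} ({verdict})"
            )
        if self.notes:
            lines += ["", "Notes", "-----"]
            lines += [f"* {note}" for note in self.notes]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "allele_table": self.allele_table.to_dict(orient="records"),
            "subtype_table": self.subtype_table.to_dict(orient="records"),
            "genotype_table": self.genotype_table.to_dict(orient="records"),
            "hwe": {
                label: {"chi2": r.chi2, "p": r.p, "expected": list(r.expected)}
                for label, r in self.hwe.items()
            },
            "notes": list(self.notes),
        }


def _allele_rows(case: AlleleCounts, control: AlleleCounts) -> tuple[list[dict], AssocResult]:
    table = ContingencyTable2x2(case.n_T, case.n_G, control.n_T, control.n_G)
    res = compare_2x2(table)
    rows = []
    for ac in (case, control):
        f_G, f_T = frequencies([ac.n_G, ac.n_T])
        rows.append(
            {
                "cohort": ac.label,
                "n_G": ac.n_G,
                "n_T": ac.n_T,
                "freq_pct": 100 * f_T,
                "chi2": res.chi2,
                "p": res.p,
                "OR": res.or_,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "method": res.method,
            }
        )
    return rows, res


def association_report(
    case_gc: GenotypeCounts,
    control_gc: GenotypeCounts,
    subtype_alleles: Sequence[AlleleCounts] = (),
    case_alleles: AlleleCounts | None = None,
    control_alleles: AlleleCounts | None = None,
) -> AssociationReport:
    """Assemble the full three-table association report.

    Allele-level counts default to those derived from the genotype counts;
    explicit ``case_alleles``/``control_alleles`` override them (a published
    table may print allele counts of its own). Any disagreement between the
    two sources is flagged in ``notes`` rather than resolved.
    """
    notes: list[str] = []
    derived_case, derived_control = allele_counts(case_gc), allele_counts(control_gc)
    case_ac = case_alleles or derived_case
    control_ac = control_alleles or derived_control
    for given, derived in ((case_ac, derived_case), (control_ac, derived_control)):
        if (given.n_G, given.n_T) != (derived.n_G, derived.n_T):
            notes.append(
                f"{given.label}: supplied allele counts {given.n_G} G / {given.n_T} T "
                f"disagree with genotype-derived {derived.n_G} G / {derived.n_T} T; "
                "allele-level table uses the supplied counts"
            )

    allele_rows, _ = _allele_rows(case_ac, control_ac)
    allele_table = pd.DataFrame(allele_rows)

    subtype_rows = []
    for sub in subtype_alleles:
        table = ContingencyTable2x2(sub.n_T, sub.n_G, control_ac.n_T, control_ac.n_G)
        res = compare_2x2(table)
        f_T = frequencies([sub.n_G, sub.n_T])[1]
        subtype_rows.append(
            {
                "subtype": sub.label,
                "n_G": sub.n_G,
                "n_T": sub.n_T,
                "freq_pct": 100 * f_T,
                "chi2": res.chi2,
                "p": res.p,
                "OR": res.or_,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "method": res.method,
            }
        )
    subtype_table = pd.DataFrame(
        subtype_rows,
        columns=["subtype", "n_G", "n_T", "freq_pct", "chi2", "p", "OR",
                 "ci_low", "ci_high", "method"],
    )

    genotype_rows = []
    case_counts = dict(zip(GENOTYPES, case_gc.as_tuple()))
    control_counts = dict(zip(GENOTYPES, control_gc.as_tuple()))
    for g in (GG, GT, TT):
        a, c = case_counts[g], control_counts[g]
        table = ContingencyTable2x2(a, case_gc.size - a, c, control_gc.size - c)
        res = compare_2x2(table)
        genotype_rows.append(
            {
                "genotype": g,
                "case_n": a,
                "case_pct": 100 * a / case_gc.size,
                "control_n": c,
                "control_pct": 100 * c / control_gc.size,
                "chi2": res.chi2,
                "p": res.p,
                "OR": res.or_,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "method": res.method,
            }
        )
    genotype_table = pd.DataFrame(genotype_rows)

    hwe = {gc.label: hwe_test(gc) for gc in (case_gc, control_gc)}
    return AssociationReport(
        allele_table=allele_table,
        subtype_table=subtype_table,
        genotype_table=genotype_table,
        hwe=hwe,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# CSV IO and the packaged study-count fixtures


def read_genotype_counts_csv(path: str | Path) -> list[GenotypeCounts]:
    """Read cohorts from CSV with columns cohort, n_GG, n_GT, n_TT."""
    df = pd.read_csv(path)
    required = {"cohort", "n_GG", "n_GT", "n_TT"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: expected columns {sorted(required)}")
    return [
        GenotypeCounts(str(r.cohort), int(r.n_GG), int(r.n_GT), int(r.n_TT))
        for r in df.itertuples()
    ]


def read_allele_counts_csv(path: str | Path) -> list[AlleleCounts]:
    """Read cohorts from CSV with columns cohort, n_G, n_T."""
    df = pd.read_csv(path)
    required = {"cohort", "n_G", "n_T"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: expected columns {sorted(required)}")
    return [AlleleCounts(str(r.cohort), int(r.n_G), int(r.n_T)) for r in df.itertuples()]


def load_study_counts() -> dict:
    """Packaged published study counts: genotype and allele tables per cohort.

    Returns a dict with GenotypeCounts for cases/controls, AlleleCounts as
    printed for each cohort, and the two leukemia-subtype allele tables.
    """
    data_dir = Path(__file__).parent / "data"
    genotype = {g.label: g for g in read_genotype_counts_csv(data_dir / "study_genotype_counts.csv")}
    allele = {a.label: a for a in read_allele_counts_csv(data_dir / "study_allele_counts.csv")}
    return {
        "case_genotypes": genotype["leukemia_patients"],
        "control_genotypes": genotype["healthy_donors"],
        "case_alleles": allele["leukemia_patients"],
        "control_alleles": allele["healthy_donors"],
        "subtype_alleles": [allele["lymphocytic_leukemia"], allele["myeloid_leukemia"]],
    }
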