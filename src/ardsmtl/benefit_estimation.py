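"""Early-vs-late ARDS diagnosis mortality comparison.

Patients positive for the strict ARDS definition (code plus SpO2 below 91%)
are split by whether their clinical diagnosis code was entered before
("early") or after ("late") the model's prediction time, and in-hospital
mortality is compared between the groups with a self-contained two-sided
Fisher exact test. Baseline mortality in the populations with and without
the strict ARDS label is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .outcome_labels import LabelSet

#: relative tolerance when comparing table probabilities in the two-sided sum
_REL_TOL = 1e-7


class UndefinedTestError(ValueError):
    """Fisher test undefined: a row or column margin is zero."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (rows: early/late diagnosis group, columns: died/survived)."""

    a: int  # early, died
    b: int  # early, survived
    c: int  # late, died
    d: int  # late, survived

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("table entries must be nonnegative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass
class BenefitReport:
    table: ContingencyTable2x2
    early_mortality_pct: float
    late_mortality_pct: float
    no_ards_mortality_pct: float | None
    ards_mortality_pct: float | None
    fisher_p: float | None
    warning: str | None = None


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the minimum-likelihood method.

    Sums hypergeometric probabilities (log-space, no overflow) of every table
    with the observed margins whose probability does not exceed the observed
    table's (within relative tolerance 1e-7).
    """
    r1, r2, c1, _ = table.margins()
    n = table.n
    if n == 0:
        raise UndefinedTestError("empty table")
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        # a zero margin leaves a single admissible table: the test is vacuous
        return 1.0
    # P(A = a) with A ~ Hypergeometric(n, r1, c1), log-space via log-binomials
    a_min = max(0, c1 - r2)
    a_max = min(r1, c1)
    support = np.arange(a_min, a_max + 1)

    def log_binom(top: float | np.ndarray, bottom: np.ndarray) -> np.ndarray:
        return gammaln(top + 1) - gammaln(bottom + 1) - gammaln(top - bottom + 1)

    logp = (
        log_binom(r1, support)
        + log_binom(r2, c1 - support)
        - log_binom(n, np.asarray(c1))
    )
    log_obs = logp[table.a - a_min]
    keep = logp <= log_obs + np.log1p(_REL_TOL)
    if keep.all():
        return 1.0  # the observed table is modal: every table contributes
    p = float(np.exp(logp[keep]).sum())
    return min(p, 1.0)


def build_benefit_table(
    label_sets: list[LabelSet],
) -> tuple[ContingencyTable2x2, float | None, float | None, str | None]:
    """Cross-tabulate diagnosis timing against in-hospital death.

    Returns the 2x2 table, baseline mortality percentages for the
    strict-ARDS-negative and -positive populations, and a warning string when
    either timing group is empty (the test is then skipped downstream).
    """
    a = b = c = d = 0
    ards_deaths = ards_n = other_deaths = other_n = 0
    for ls in label_sets:
        if ls.ards_1:
            ards_n += 1
            ards_deaths += int(ls.death_12)
            if ls.diagnosis_timing == "early":
                a += int(ls.death_12)
                b += int(not ls.death_12)
            elif ls.diagnosis_timing == "late":
                c += int(ls.death_12)
                d += int(not ls.death_12)
            else:  # pragma: no cover - derive_labels always sets a timing
                raise ValueError("strict-ARDS-positive patient without timing")
        else:
            other_n += 1
            other_deaths += int(ls.death_12)
    table = ContingencyTable2x2(a, b, c, d)
    no_ards_pct = 100.0 * other_deaths / other_n if other_n else None
    ards_pct = 100.0 * ards_deaths / ards_n if ards_n else None
    warning = None
    if a + b == 0 or c + d == 0:
        warning = "empty early or late diagnosis group; Fisher test skipped"
    return table, no_ards_pct, ards_pct, warning


def benefit_report(label_sets: list[LabelSet]) -> BenefitReport:
    """Assemble mortality percentages and the Fisher p for a labeled cohort."""
    table, no_ards_pct, ards_pct, warning = build_benefit_table(label_sets)
    return report_from_table(table, no_ards_pct, ards_pct, warning)


def report_from_table(
    table: ContingencyTable2x2,
    no_ards_pct: float | None = None,
    ards_pct: float | None = None,
    warning: str | None = None,
) -> BenefitReport:
    """Benefit report directly from a 2x2 table (plus optional baselines)."""
    early_n = table.a + table.b
    late_n = table.c + table.d
    early_pct = 100.0 * table.a / early_n if early_n else float("nan")
    late_pct = 100.0 * table.c / late_n if late_n else float("nan")
    fisher_p = None
    if warning is None and early_n > 0 and late_n > 0:
        try:
            fisher_p = fisher_exact_two_sided(table)
        except UndefinedTestError:
            warning = "degenerate column margin; Fisher test skipped"
    return BenefitReport(
        table=table,
        early_mortality_pct=early_pct,
        late_mortality_pct=late_pct,
        no_ards_mortality_pct=no_ards_pct,
        ards_mortality_pct=ards_pct,
        fisher_p=fisher_p,
        warning=warning,
    )


def format_report(report: BenefitReport) -> str:
    """Human-readable rendering, group rates to 1 decimal, baselines to 2."""
    t = report.table
    lines = [
        "Early-vs-late ARDS diagnosis mortality",
        f"  early group: {t.a}/{t.a + t.b} died ({report.early_mortality_pct:.1f}%)",
        f"  late group:  {t.c}/{t.c + t.d} died ({report.late_mortality_pct:.1f}%)",
    ]
    if report.no_ards_mortality_pct is not None:
        lines.append(f"  baseline, no strict ARDS: {report.no_ards_mortality_pct:.2f}%")
    if report.ards_mortality_pct is not None:
        lines.append(f"  baseline, strict ARDS:    {report.ards_mortality_pct:.2f}%")
    if report.fisher_p is not None:
        lines.append(f"  two-sided Fisher exact p: {report.fisher_p:.3f}")
    if report.warning:
        lines.append(f"  warning: {report.warning}")
    return "\n".join(lines)
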