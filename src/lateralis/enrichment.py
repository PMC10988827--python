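"""Case-control allele enrichment statistics.

Builds allele-based 2x2 contingency tables from case genotypes and control
allele counts, estimates the odds ratio with a Wald 95% confidence
interval (Haldane-Anscombe 0.5 correction only when a cell is zero), tests
association with Fisher's exact test, and computes the expected number of
variant alleles under the control frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "build_allele_table",
    "build_carrier_table",
    "odds_ratio_wald",
    "fisher_exact",
    "enrich",
    "expected_variant_alleles",
]

#: two-sided 95% normal quantile used for the Wald interval
Z_95 = 1.959964


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cells: a/b = case variant/reference, c/d = control variant/reference."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell in 2x2 table: {cells}")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("both case and control margins must be positive")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass
class EnrichmentResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float | None
    correction_applied: bool
    table: ContingencyTable2x2

    def rounded(self, ndigits: int = 1):
        """(OR, CI low, CI high) rounded for reporting."""
        return (
            round(self.odds_ratio, ndigits),
            round(self.ci_low, ndigits),
            round(self.ci_high, ndigits),
        )


def build_allele_table(case_genotypes, n_cases: int, control_variant: int,
                       control_total: int) -> ContingencyTable2x2:
    """Allele-count table: het contributes 1 variant allele, hom 2.

    ``case_genotypes`` lists the genotype ('het'/'hom') of each carrier (or
    of every case; 'ref' entries contribute nothing).  Control counts are
    variant alleles out of total alleles.
    """
    if control_variant > control_total:
        raise ValueError("control variant alleles exceed control total")
    contribution = {"ref": 0, "het": 1, "hom": 2}
    a = 0
    for gt in case_genotypes:
        try:
            a += contribution[gt]
        except KeyError:
            raise ValueError(f"unknown genotype {gt!r}") from None
    b = 2 * n_cases - a
    if b < 0:
        raise ValueError("case variant alleles exceed 2 * n_cases")
    return ContingencyTable2x2(a=a, b=b, c=control_variant,
                               d=control_total - control_variant)


def build_carrier_table(n_carriers: int, n_cases: int, control_carriers: int,
                        control_total: int) -> ContingencyTable2x2:
    """Carrier-count table (individuals, not alleles); clearly secondary to
    the allele-based headline statistic."""
    return ContingencyTable2x2(a=n_carriers, b=n_cases - n_carriers,
                               c=control_carriers,
                               d=control_total - control_carriers)


def odds_ratio_wald(t: ContingencyTable2x2) -> EnrichmentResult:
    """Odds ratio with a Wald 95% CI on the log scale.

    If any cell is zero, 0.5 is added to every cell (Haldane-Anscombe)
    before both the estimate and the interval.
    """
    correction = t.has_zero_cell
    shift = 0.5 if correction else 0.0
    a, b, c, d = (t.a + shift, t.b + shift, t.c + shift, t.d + shift)
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return EnrichmentResult(
        odds_ratio=or_,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        p=None,
        correction_applied=correction,
        table=t,
    )


def fisher_exact(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (hypergeometric tail sum), uncorrected counts."""
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(min(p, 1.0))


def enrich(case_genotypes, n_cases, control_variant, control_total,
           mode: str = "allele") -> EnrichmentResult:
    """Full enrichment analysis: table, OR + Wald CI, and Fisher p."""
    if mode == "allele":
        t = build_allele_table(case_genotypes, n_cases, control_variant,
                               control_total)
    elif mode == "carrier":
        carriers = sum(1 for g in case_genotypes if g in ("het", "hom"))
        t = build_carrier_table(carriers, n_cases, control_variant,
                                control_total)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    result = odds_ratio_wald(t)
    result.p = fisher_exact(t)
    return result


def expected_variant_alleles(q: float, n_individuals: int) -> float:
    """Expected variant alleles among ``n`` diploid individuals: ``2 n q``."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    if n_individuals < 0:
        raise ValueError("n_individuals must be non-negative")
    return 2.0 * n_individuals * q
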