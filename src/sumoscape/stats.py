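"""2x2 enrichment statistics: Pearson chi-squared with Yates' correction.

The corrected statistic for a table ``[[a, b], [c, d]]`` with total N is

    chi2 = N * (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d))

clamped to 0 when the correction overshoots (|ad - bc| <= N/2).  The
p-value comes from the chi-squared survival function with one degree of
freedom and is inherently two-sided.  Values below the conventional
double-precision reporting floor 2.2e-16 are printed as "< 2.2e-16"
while the raw value is retained machine-readably.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2 as _chi2_dist

P_FLOOR = 2.2e-16


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = focal with property, b = focal without, c/d = background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells) or any(x != int(x) for x in cells):
            raise ValueError("cells must be non-negative integers")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    df: int = 1
    corrected: bool = True
    p_floor: float = P_FLOOR

    @property
    def p_display(self) -> str:
        """p formatted for reports, floored at the reporting limit."""
        if self.p_value < self.p_floor:
            return f"< {self.p_floor:g}"
        return f"{self.p_value:.4g}"


def yates_chi2(table: ContingencyTable2x2) -> ChiSquareResult:
    """Pearson chi-squared test with Yates' continuity correction (df=1)."""
    if min(table.margins) == 0:
        raise ValueError("zero margin: chi-squared statistic undefined")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    cross = abs(a * d - b * c)
    corrected = max(cross - n / 2, 0.0)
    r1, r2, c1, c2 = table.margins
    statistic = n * corrected**2 / (r1 * r2 * c1 * c2)
    p_value = float(_chi2_dist.sf(statistic, 1)) if statistic > 0 else 1.0
    return ChiSquareResult(statistic=float(statistic), p_value=p_value)


def conservation_enrichment(
    targets_total: int,
    targets_conserved: int,
    proteome_total: int,
    proteome_conserved: int,
) -> ChiSquareResult:
    """Are conserved proteins over-represented among SUMO targets?

    The background is the proteome minus the target set, so the four
    cells are disjoint: (conserved targets, non-conserved targets,
    conserved non-targets, non-conserved non-targets).
    """
    if targets_conserved > targets_total or proteome_conserved > proteome_total:
        raise ValueError("conserved counts exceed totals")
    if targets_total > proteome_total or targets_conserved > proteome_conserved:
        raise ValueError("target counts exceed proteome counts")
    table = ContingencyTable2x2(
        a=targets_conserved,
        b=targets_total - targets_conserved,
        c=proteome_conserved - targets_conserved,
        d=(proteome_total - targets_total) - (proteome_conserved - targets_conserved),
    )
    return yates_chi2(table)


def conservation_enrichment_whole_proteome(
    targets_total: int,
    targets_conserved: int,
    proteome_total: int,
    proteome_conserved: int,
) -> ChiSquareResult:
    """Variant using the whole proteome (targets included) as background."""
    if targets_conserved > targets_total or proteome_conserved > proteome_total:
        raise ValueError("conserved counts exceed totals")
    table = ContingencyTable2x2(
        a=targets_conserved,
        b=targets_total - targets_conserved,
        c=proteome_conserved,
        d=proteome_total - proteome_conserved,
    )
    return yates_chi2(table)


def motif_enrichment(
    set1_total: int,
    set1_with_motif: int,
    set2_total: int,
    set2_with_motif: int,
) -> ChiSquareResult:
    """Compare motif prevalence between two protein sets."""
    if set1_with_motif > set1_total or set2_with_motif > set2_total:
        raise ValueError("with-motif counts exceed totals")
    table = ContingencyTable2x2(
        a=set1_with_motif,
        b=set1_total - set1_with_motif,
        c=set2_with_motif,
        d=set2_total - set2_with_motif,
    )
    return yates_chi2(table)
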