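"""Cross-scheme trend standardization.

Monitoring schemes publish total-abundance changes over different spans;
comparison requires converting cumulative percent changes to annualized
geometric-mean rates (and back):

    annual = 100 * ((1 + cumulative/100)^(1/span) - 1)

The published summaries of the three long-running European schemes (and
the Ohio-style scheme this package emulates) are bundled as reference
rows; ``build_comparison_table`` recomputes each scheme's annual rate from
its printed cumulative value and flags internal inconsistencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "SchemeSummary",
    "cumulative_to_annual",
    "annual_to_cumulative",
    "build_comparison_table",
    "EUROPEAN_SCHEMES",
]


@dataclass
class SchemeSummary:
    """Published summary of one monitoring scheme's total-abundance trend."""

    region: str
    span_years: int
    n_sites: int
    cumulative_percent: float
    annual_percent: float
    species_positive: int | None = None
    species_negative: int | None = None
    species_stable: int | None = None


def cumulative_to_annual(cumulative_percent: float, span_years: int) -> float:
    """Annualized geometric-mean percent rate from a cumulative change."""
    if span_years < 1:
        raise ValueError("span_years must be >= 1")
    if cumulative_percent <= -100:
        raise ValueError("cumulative change must exceed -100%")
    return 100.0 * ((1.0 + cumulative_percent / 100.0) ** (1.0 / span_years) - 1.0)


def annual_to_cumulative(annual_percent: float, span_years: int) -> float:
    """Cumulative percent change from an annual rate (exact inverse)."""
    if span_years < 1:
        raise ValueError("span_years must be >= 1")
    if annual_percent <= -100:
        raise ValueError("annual rate must exceed -100%")
    return 100.0 * ((1.0 + annual_percent / 100.0) ** span_years - 1.0)


# Published summaries: three European schemes plus the Ohio-style scheme.
# UK reports two indicator groups (countryside/specialist) over one scheme;
# the UK species tallies apply to the scheme as a whole and are attached to
# both rows.
EUROPEAN_SCHEMES: list[SchemeSummary] = [
    SchemeSummary("United Kingdom (countryside)", 41, 3164, -28.0, -0.8, 11, 22, 24),
    SchemeSummary("United Kingdom (specialist)", 41, 3164, -63.0, -2.4, 11, 22, 24),
    SchemeSummary("Netherlands", 25, 600, -40.0, -2.0, 11, 23, 13),
    SchemeSummary("Catalonia, Spain", 22, 116, -44.0, -2.6, 15, 46, 5),
]

OHIO_SCHEME = SchemeSummary("Ohio, USA", 20, 104, -33.0, -2.0, 9, 32, 40)


def build_comparison_table(
    schemes: list[SchemeSummary],
    tolerance_pp: float = 0.05,
) -> pd.DataFrame:
    """Comparison table with annual rates recomputed from cumulative values.

    One row per scheme; ``inconsistent`` flags schemes whose printed annual
    rate differs from the recomputed one by more than ``tolerance_pp``
    percentage points after rounding both to 1 decimal.
    """
    if not schemes:
        raise ValueError("need at least one scheme")
    rows = []
    for s in schemes:
        recomputed = cumulative_to_annual(s.cumulative_percent, s.span_years)
        rows.append(
            {
                "region": s.region,
                "span_years": s.span_years,
                "n_sites": s.n_sites,
                "cumulative_percent": s.cumulative_percent,
                "annual_percent_printed": s.annual_percent,
                "annual_percent_recomputed": recomputed,
                "inconsistent": bool(
                    abs(round(recomputed, 1) - round(s.annual_percent, 1))
                    > tolerance_pp
                ),
                "species_positive": s.species_positive,
                "species_negative": s.species_negative,
                "species_stable": s.species_stable,
            }
        )
    return pd.DataFrame(rows)
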