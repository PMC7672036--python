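"""Single-cell PCR validation statistics.

Before clinical use, a single-cell assay is validated on a panel of single
lymphocytes from the couple.  Three rates summarise the workup:

* cell amplification rate — cells giving any signal / cells attempted;
* ADO rate — amplified cells affected by allele drop-out / amplified cells;
* successful amplification rate — amplified cells with both alleles
  recovered / amplified cells (the complement of the ADO rate).

Each rate carries a Wilson 95% interval, which behaves sensibly at the
small counts typical of these panels.  Blank (wash-drop) controls must all
be negative for the panel to be credible.
"""

from __future__ import annotations

from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

from .model import ConfigError


@dataclass(frozen=True)
class QcCounts:
    """Raw panel counts."""

    n_cells: int
    n_no_signal: int
    n_ado: int
    n_blank_controls: int = 0
    n_blank_positive: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_no_signal < 0 or self.n_ado < 0:
            raise ConfigError("counts must be non-negative")
        if self.n_no_signal + self.n_ado > self.n_cells:
            raise ConfigError("n_no_signal + n_ado cannot exceed n_cells")
        if self.n_blank_positive > self.n_blank_controls:
            raise ConfigError("n_blank_positive cannot exceed n_blank_controls")


@dataclass(frozen=True)
class RateEstimate:
    """A proportion with its Wilson 95% interval."""

    value: float
    ci_low: float
    ci_high: float

    @property
    def pct(self) -> float:
        """The rate in percent, rounded to one decimal."""
        return round(self.value * 100, 1)


@dataclass(frozen=True)
class QcRates:
    n_amplified: int
    cell_amplification_rate: RateEstimate | None
    ado_rate: RateEstimate | None
    success_rate: RateEstimate | None
    message: str | None = None


def _wilson(k: int, n: int) -> RateEstimate:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return RateEstimate(value=k / n, ci_low=float(lo), ci_high=float(hi))


def qc_rates(counts: QcCounts) -> QcRates:
    """Compute the three panel rates with Wilson 95% intervals.

    The ADO denominator is amplified cells, not attempted cells: a cell that
    never amplified cannot exhibit allele drop-out.  With zero amplified
    cells the rates are undefined and returned as None with a message.
    """
    amplified = counts.n_cells - counts.n_no_signal
    if counts.n_cells == 0 or amplified == 0:
        return QcRates(
            n_amplified=amplified,
            cell_amplification_rate=None,
            ado_rate=None,
            success_rate=None,
            message="no amplified cells: rates undefined",
        )
    return QcRates(
        n_amplified=amplified,
        cell_amplification_rate=_wilson(amplified, counts.n_cells),
        ado_rate=_wilson(counts.n_ado, amplified),
        success_rate=_wilson(amplified - counts.n_ado, amplified),
    )


def validate_blanks(counts: QcCounts) -> tuple[bool, str]:
    """Pass iff no blank control amplified."""
    if counts.n_blank_controls == 0:
        return True, "pass (warning: no blank controls run)"
    if counts.n_blank_positive == 0:
        return True, f"pass: 0/{counts.n_blank_controls} blank controls amplified"
    return (
        False,
        f"fail: {counts.n_blank_positive}/{counts.n_blank_controls} blank controls "
        "amplified — contamination suspected",
    )
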