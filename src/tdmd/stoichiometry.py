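"""Absolute quantification and stoichiometry arithmetic.

A qPCR standard curve (Cq vs log10 input copies, ordinary least squares)
converts measured Cq values into copies per cell (cpc). The target-per-miRNA
(TPM) ratio — target cpc divided by miRNA cpc — summarises the stoichiometry
of a putative TDMD interaction; degradation is effective from TPM >= 1 and
strongest at ratios above ~10-40. Half-life arithmetic assumes pure
exponential loss with negligible synthesis over the measured window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("tdmd")


@dataclass
class StandardCurve:
    """OLS fit of Cq against log10(copies); efficiency = 10^(-1/slope) - 1."""

    slope: float
    intercept: float
    r2: float
    efficiency: float
    log10_range: tuple[float, float]

    def cq(self, copies: float) -> float:
        return self.intercept + self.slope * np.log10(copies)

    def copies(self, cq: float) -> float:
        return 10 ** ((cq - self.intercept) / self.slope)


@dataclass
class StoichiometryState:
    species: str
    cpc: float
    condition: str
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.cpc) or self.cpc < 0:
            raise ValueError("copies per cell must be finite and >= 0")


@dataclass
class TPMRatio:
    target_cpc: float
    mirna_cpc: float

    @property
    def tpm(self) -> float:
        return self.target_cpc / self.mirna_cpc


def fit_standard_curve(points) -> StandardCurve:
    """Fit a titration series of (known_copies, measured_Cq) pairs.

    Requires >= 3 points; warns when the dilution series spans less than two
    orders of magnitude.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("standard curve requires >= 3 (copies, Cq) points")
    copies, cq = pts[:, 0], pts[:, 1]
    if (copies <= 0).any():
        raise ValueError("known copies must be positive")
    x = np.log10(copies)
    if x.max() - x.min() < 2:
        logger.warning("standards span < 2 orders of magnitude")
    fit = stats.linregress(x, cq)
    efficiency = 10 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        slope=fit.slope,
        intercept=fit.intercept,
        r2=fit.rvalue**2,
        efficiency=efficiency,
        log10_range=(x.min(), x.max()),
    )


def copies_per_cell(
    measured_cq: float,
    curve: StandardCurve,
    cells_per_rxn: float,
    species: str = "",
    condition: str = "",
) -> StoichiometryState:
    """Invert the standard curve and scale to a per-cell quantity.

    Cq values outside the calibrated range are converted but flagged as
    extrapolated.
    """
    if cells_per_rxn <= 0:
        raise ValueError("cells_per_rxn must be positive")
    copies = curve.copies(measured_cq)
    lo, hi = curve.log10_range
    extrapolated = not (lo - 1e-9 <= np.log10(copies) <= hi + 1e-9)
    if extrapolated:
        logger.warning("Cq %.2f outside calibrated range", measured_cq)
    return StoichiometryState(
        species=species,
        cpc=copies / cells_per_rxn,
        condition=condition,
        extrapolated=extrapolated,
    )


def tpm_ratio(target: StoichiometryState, mirna: StoichiometryState) -> TPMRatio:
    """Target-per-miRNA ratio; both measurements must share a condition."""
    if target.condition != mirna.condition:
        raise ValueError(
            f"conditions differ: {target.condition!r} vs {mirna.condition!r}"
        )
    if mirna.cpc <= 0:
        raise ZeroDivisionError("miRNA copies per cell must be positive")
    return TPMRatio(target_cpc=target.cpc, mirna_cpc=mirna.cpc)


def pooled_cpc(states: list[StoichiometryState], species: str = "pool") -> StoichiometryState:
    """Summed copies over a family subset (pooled TPM denominator)."""
    if not states:
        raise ValueError("empty pool")
    conditions = {s.condition for s in states}
    if len(conditions) > 1:
        raise ValueError("pooled members must share a condition")
    return StoichiometryState(
        species=species,
        cpc=float(sum(s.cpc for s in states)),
        condition=states[0].condition,
    )


def half_life_from_log2fc(log2fc: float, elapsed_h: float) -> float:
    """Apparent half-life (h) from an observed log2 fold-change.

    Assumes pure exponential loss with negligible synthesis over the window:
    t_half = -elapsed_h / log2fc. A log2 FC of -1 over 4 h gives 4 h.
    """
    if log2fc >= 0:
        raise ValueError("no decay: log2 fold-change must be negative")
    if elapsed_h <= 0:
        raise ValueError("elapsed time must be positive")
    return -elapsed_h / log2fc
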