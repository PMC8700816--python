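"""Closed-form formulation metrics.

Small, exactly-defined quantities used when characterizing emulsion
formulations and antimicrobial combinations: the Sauter (surface-weighted)
mean droplet diameter d3.2, DPPH radical-scavenging inhibition and its
IC50, the droplet growth ratio tracked in storage-stability studies, and
the fractional inhibitory concentration index (FICI) from checkerboard
assays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SizeDistribution",
    "DoseResponse",
    "MicStructure",
    "sauter_mean",
    "dpph_inhibition",
    "ic50",
    "droplet_growth_ratio",
    "fici",
    "FICI_CATEGORIES",
]


@dataclass(frozen=True)
class SizeDistribution:
    """Binned droplet-size counts: (diameter d_i, count n_i) pairs."""

    diameters: tuple[float, ...]
    counts: tuple[float, ...]

    def __init__(self, diameters, counts) -> None:
        d = np.asarray(diameters, dtype=float)
        n = np.asarray(counts, dtype=float)
        if d.shape != n.shape or d.ndim != 1 or d.size == 0:
            raise ValueError("diameters and counts must be equal-length 1-d sequences")
        if (d <= 0).any():
            raise ValueError("all diameters must be positive")
        if (n < 0).any():
            raise ValueError("counts must be non-negative")
        if not (n > 0).any():
            raise ValueError("at least one bin must have a positive count")
        object.__setattr__(self, "diameters", tuple(d.tolist()))
        object.__setattr__(self, "counts", tuple(n.tolist()))


def sauter_mean(dist: SizeDistribution) -> float:
    """Sauter mean diameter d3.2 = sum(n d^3) / sum(n d^2), same units as d."""
    d = np.asarray(dist.diameters)
    n = np.asarray(dist.counts)
    denom = float((n * d**2).sum())
    if denom <= 0:
        raise ZeroDivisionError("zero surface area: Sauter mean undefined")
    return float((n * d**3).sum() / denom)


def dpph_inhibition(a_blank: float, a_sample: float) -> float:
    """DPPH inhibition I(%) = 100 * (A_blank - A_sample) / A_blank."""
    if a_blank <= 0:
        raise ValueError("blank absorbance must be positive")
    return 100.0 * (a_blank - a_sample) / a_blank


@dataclass(frozen=True)
class DoseResponse:
    """Inhibition (%) measured at strictly increasing concentrations (mg/mL)."""

    concentrations: tuple[float, ...]
    inhibitions: tuple[float, ...]

    def __init__(self, concentrations, inhibitions) -> None:
        c = np.asarray(concentrations, dtype=float)
        i = np.asarray(inhibitions, dtype=float)
        if c.shape != i.shape or c.ndim != 1 or c.size < 2:
            raise ValueError("need at least two (concentration, inhibition) points")
        if (c <= 0).any():
            raise ValueError("concentrations must be positive")
        if (np.diff(c) <= 0).any():
            raise ValueError("concentrations must be strictly increasing")
        if (i > 100).any():
            raise ValueError("inhibition cannot exceed 100%")
        object.__setattr__(self, "concentrations", tuple(c.tolist()))
        object.__setattr__(self, "inhibitions", tuple(i.tolist()))


def ic50(dr: DoseResponse, level: float = 50.0, allow_decreasing: bool = False) -> float:
    """Concentration at ``level``% inhibition by log-linear interpolation.

    Interpolates inhibition against log10(concentration) between the first
    adjacent pair bracketing the level (serial dilutions are geometric, so
    the log scale is the natural interpolation axis).  An exact hit is
    returned directly.  With ``allow_decreasing`` the level may also be
    bracketed on a decreasing segment.
    """
    c = np.asarray(dr.concentrations)
    i = np.asarray(dr.inhibitions)
    exact = np.isclose(i, level)
    if exact.any():
        return float(c[int(np.argmax(exact))])
    for k in range(len(c) - 1):
        lo, hi = i[k], i[k + 1]
        rising = lo < level < hi
        falling = hi < level < lo
        if rising or (falling and allow_decreasing):
            lc = np.log10(c[k : k + 2])
            t = (level - lo) / (hi - lo)
            return float(10 ** (lc[0] + t * (lc[1] - lc[0])))
    raise ValueError(
        f"{level}% inhibition is not bracketed by the assay points "
        "(out-of-range dose response)"
    )


def droplet_growth_ratio(d_n: float, d_0: float) -> float:
    """Relative droplet growth R = (d_n - d_0) / d_0 over a storage period."""
    if d_0 <= 0:
        raise ValueError("initial diameter must be positive")
    return (d_n - d_0) / d_0


@dataclass(frozen=True)
class MicStructure:
    """Checkerboard MICs: each agent alone and in the combination (ug/mL)."""

    mic_a_alone: float
    mic_b_alone: float
    mic_a_combo: float
    mic_b_combo: float

    def __post_init__(self) -> None:
        for v in (self.mic_a_alone, self.mic_b_alone, self.mic_a_combo, self.mic_b_combo):
            if v <= 0:
                raise ValueError("all MICs must be positive")


#: conventional checkerboard breakpoints: (upper bound, category)
FICI_CATEGORIES: tuple[tuple[float, str], ...] = (
    (0.5, "synergy"),
    (1.0, "additive"),
    (4.0, "indifferent"),
    (float("inf"), "antagonism"),
)


def fici(m: MicStructure, categories=FICI_CATEGORIES) -> tuple[float, str]:
    """Fractional inhibitory concentration index and its category.

    FICI = MIC_A,combo/MIC_A,alone + MIC_B,combo/MIC_B,alone.  The default
    breakpoints are the conventional checkerboard ones (<=0.5 synergy,
    <=1 additive, <=4 indifferent, >4 antagonism); pass custom
    ``categories`` (sorted (upper_bound, label) pairs, upper bound
    inclusive) to use a laxer synergy cut-off.
    """
    value = m.mic_a_combo / m.mic_a_alone + m.mic_b_combo / m.mic_b_alone
    for bound, label in categories:
        if value <= bound:
            return value, label
    return value, categories[-1][1]
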