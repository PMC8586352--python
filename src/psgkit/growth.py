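"""Exponential-growth algebra linking LFC, assay length, and growth rate.

A pooled-screen log2 fold change over an assay of t days corresponds to a
change in exponential growth rate of delta_k = LFC / t doublings per day:
with populations X = X_i * 2^(k*t), the log2 ratio of knockout to wild-type
populations grown for the same time is (k_ko - k_wt) * t.  A fixed delta_k
therefore produces a smaller observed LFC in a shorter assay, which is why
weak positive-selection phenotypes need long screens to rise above noise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DataError


@dataclass
class GrowthScenario:
    """Kinetic summary of one knockout's growth-rate shift."""

    lfc: float
    t: float  # days
    k_wt: float  # doublings/day
    delta_k: float
    doubling_time_wt_hours: float
    doubling_time_ko_hours: float
    fitness_increase_percent: float

    @classmethod
    def from_lfc(cls, lfc: float, t: float, k_wt: float = 1.0) -> "GrowthScenario":
        dk = delta_k_from_lfc(lfc, t)
        return cls(
            lfc=lfc, t=t, k_wt=k_wt, delta_k=dk,
            doubling_time_wt_hours=doubling_time_hours(k_wt, 0.0),
            doubling_time_ko_hours=doubling_time_hours(k_wt, dk),
            fitness_increase_percent=100.0 * dk / k_wt,
        )


def delta_k_from_lfc(lfc: float, t: float) -> float:
    """Growth-rate change (doublings/day) implied by an LFC over t days."""
    if t <= 0:
        raise DataError("assay duration t must be > 0 days")
    return lfc / t


def lfc_from_delta_k(delta_k: float, t: float) -> float:
    """LFC observed after t days for a growth-rate change delta_k."""
    if t <= 0:
        raise DataError("assay duration t must be > 0 days")
    return delta_k * t


def doubling_time_hours(k_wt: float = 1.0, delta_k: float = 0.0) -> float:
    """Population doubling time in hours at rate k_wt + delta_k doublings/day."""
    k = k_wt + delta_k
    if k <= 0:
        raise DataError("net growth rate must be positive")
    return 24.0 / k


def project_population(x_i: float, k: float, t: float) -> float:
    """Cells after t days growing at k doublings/day from x_i cells."""
    if x_i <= 0:
        raise DataError("initial population must be > 0")
    return x_i * 2.0 ** (k * t)
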