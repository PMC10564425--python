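"""Ferroptosis Potential Index (FPI) computation and sample stratification.

The FPI of a sample is the ssGSEA enrichment score of the positive
ferroptosis regulators minus that of the negative regulators: samples with
high FPI are inferred to have high ferroptosis activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GeneSet, GeneSetCollection, InputError
from .enrichment import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FRGConfig",
    "FPIVector",
    "compute_fpi",
    "standardize_fpi",
    "assign_groups",
    "starter_frg_sets",
    "POSITIVE_FRG",
    "NEGATIVE_FRG",
]

# Starter ferroptosis-regulator panel: 12 positive drivers (lipid-peroxidation
# promoting) and 4 negative suppressors (mevalonate/CoQ10 axis).  The negative
# list is known to be incomplete — published panels add further suppressors —
# so production analyses should supply their own GMT.
POSITIVE_FRG = (
    "LPCAT3", "NCOA4", "ACSL4", "GPX4", "SLC3A2", "ALOX15",
    "SLC7A11", "NOX5", "NFE2L2", "NOX3", "NOX1", "NOX4",
)
NEGATIVE_FRG = ("FDFT1", "COQ10A", "HMGCR", "COQ10B")


def starter_frg_sets() -> "FRGConfig":
    """The documented starter positive/negative regulator panel."""
    return FRGConfig(
        positive=GeneSet("FRG_positive", "positive ferroptosis regulators", frozenset(POSITIVE_FRG)),
        negative=GeneSet("FRG_negative", "negative ferroptosis regulators (incomplete starter)", frozenset(NEGATIVE_FRG)),
    )


@dataclass
class FRGConfig:
    """Positive/negative ferroptosis-regulator gene sets (disjoint, non-empty)."""

    positive: GeneSet
    negative: GeneSet

    def __post_init__(self) -> None:
        overlap = self.positive.members & self.negative.members
        if overlap:
            raise InputError(f"positive and negative FRG sets overlap: {sorted(overlap)}")

    def as_collection(self) -> GeneSetCollection:
        return GeneSetCollection([self.positive, self.negative])


@dataclass
class FPIVector:
    """Per-sample FPI values, optionally min-max standardized and grouped."""

    sample_ids: list[str]
    fpi: np.ndarray
    standardized: bool = False
    group: np.ndarray | None = None  # "low"/"high" after a cutoff is applied

    def __post_init__(self) -> None:
        self.fpi = np.asarray(self.fpi, dtype=float)
        if self.fpi.shape != (len(self.sample_ids),):
            raise InputError("FPI vector length does not match sample ids")
        if not np.all(np.isfinite(self.fpi)):
            raise InputError("FPI values must be finite")
        if self.standardized and (self.fpi.min() < 0 or self.fpi.max() > 1):
            raise InputError("standardized FPI must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"fpi": self.fpi}, index=self.sample_ids)
        if self.group is not None:
            out["group"] = self.group
        out.index.name = "sample_id"
        return out


def compute_fpi(scores: ScoreMatrix, frg: FRGConfig) -> FPIVector:
    """FPI = ES(positive regulators) - ES(negative regulators), per sample."""
    for name in (frg.positive.name, frg.negative.name):
        if name not in scores.set_names:
            raise InputError(f"score matrix lacks the {name!r} row")
    fpi = scores.row(frg.positive.name) - scores.row(frg.negative.name)
    return FPIVector(list(scores.sample_ids), fpi)


def standardize_fpi(fpi: FPIVector) -> FPIVector:
    """Min-max rescale FPI to [0, 1] (order preserving)."""
    lo, hi = fpi.fpi.min(), fpi.fpi.max()
    if hi == lo:
        raise InputError("cannot standardize a constant FPI vector")
    return FPIVector(list(fpi.sample_ids), (fpi.fpi - lo) / (hi - lo), standardized=True)


def assign_groups(fpi: FPIVector, cutoff: float) -> FPIVector:
    """Label samples low (fpi < cutoff) / high (fpi >= cutoff).

    A sample exactly at the cutoff goes to the high group (strict-less rule
    for low).  The cutoff must split off two non-empty groups.
    """
    lo, hi = fpi.fpi.min(), fpi.fpi.max()
    if not (lo < cutoff <= hi):
        raise InputError(
            f"cutoff {cutoff} does not produce two non-empty groups "
            f"(observed range [{lo}, {hi}])"
        )
    group = np.where(fpi.fpi < cutoff, "low", "high")
    n_low = int((group == "low").sum())
    logger.info("assign_groups: %d low / %d high at cutoff %g", n_low, len(group) - n_low, cutoff)
    return FPIVector(list(fpi.sample_ids), fpi.fpi.copy(), fpi.standardized, group)
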