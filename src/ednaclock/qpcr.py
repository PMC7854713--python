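"""Standard-curve quantification and detection-limit censoring.

qPCR quantifies template by the cycle (Cq) at which fluorescence
crosses a threshold.  A dilution series of known copy numbers gives a
standard curve, Cq = intercept + slope * log10(copies); perfect
doubling per cycle corresponds to slope = -log2(10) ~ -3.3219, i.e.
100 % amplification efficiency.  Samples whose Cq exceeds a detection
threshold (default 35 cycles), or which never amplify, are censored
non-detects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import ValidationError

log = logging.getLogger("ednaclock")

#: Cq threshold above which an amplification is treated as a non-detect.
DEFAULT_CQ_THRESHOLD = 35.0

#: mL of filtered water represented by one reaction, for the default
#: protocol: 2.5 uL template from a 75 uL eluate of a half filter that
#: captured 100 mL of water -> (2.5 / 75) * (100 / 2) = 5/3 mL.
DEFAULT_TEMPLATE_VOLUME_EQ_ML = (2.5 / 75.0) * (100.0 / 2.0)


class InvalidCurveError(ValidationError):
    """The dilution series does not define a usable standard curve."""


@dataclass(frozen=True)
class StandardCurve:
    """Linear standard curve Cq = intercept + slope * log10(copies).

    ``efficiency`` is the per-cycle amplification gain minus one, as a
    fraction (1.0 = 100 %): efficiency = 10^(-1/slope) - 1.
    """

    slope: float
    intercept: float
    r2: float
    efficiency: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise InvalidCurveError(f"slope must be negative, got {self.slope}")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValidationError(f"r2 must lie in [0, 1], got {self.r2}")


@dataclass(frozen=True)
class CqRecord:
    """One qPCR well: sample label, target label, Cq (None = no amplification)."""

    sample: str
    target: str
    cq: Optional[float] = None
    censored: bool = False

    def __post_init__(self) -> None:
        if self.cq is not None and self.cq <= 0:
            raise ValidationError(f"cq must be positive when present, got {self.cq}")


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency (fraction) implied by a standard-curve slope."""
    if slope >= 0:
        raise InvalidCurveError(f"slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(
    dilutions: Sequence[Tuple[float, float]]
) -> StandardCurve:
    """Ordinary least squares of Cq on log10(copies per reaction).

    Parameters
    ----------
    dilutions : sequence of (copies_per_reaction, cq)
        At least 3 distinct positive copy levels.
    """
    if any(c <= 0 for c, _ in dilutions):
        raise ValidationError("copies_per_reaction must be > 0")
    levels = {c for c, _ in dilutions}
    if len(levels) < 3:
        raise ValidationError(
            f"need >= 3 distinct dilution levels, got {len(levels)}"
        )
    x = np.log10([c for c, _ in dilutions])
    y = np.asarray([q for _, q in dilutions], dtype=float)
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise InvalidCurveError(
            f"fitted slope {res.slope:.4f} is non-negative; not a valid curve"
        )
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        efficiency=efficiency_from_slope(float(res.slope)),
    )


def cq_to_copies(cq: Optional[float], curve: StandardCurve) -> Optional[float]:
    """Invert the standard curve: copies = 10^((cq - intercept) / slope).

    Returns None for an absent Cq (no amplification): a censored marker,
    never a number.
    """
    if cq is None:
        return None
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def apply_detection_limit(
    records: Sequence[CqRecord], threshold_cq: float = DEFAULT_CQ_THRESHOLD
) -> List[CqRecord]:
    """Flag records with Cq > threshold, or with no amplification, as censored.

    Detections are returned unchanged; the operation is idempotent.
    """
    if threshold_cq <= 0:
        raise ValidationError("threshold_cq must be > 0")
    out: List[CqRecord] = []
    n_censored = 0
    for r in records:
        censor = r.cq is None or r.cq > threshold_cq
        n_censored += censor
        out.append(replace(r, censored=censor))
    log.info(
        "detection limit Cq > %g: %d censored, %d retained",
        threshold_cq,
        n_censored,
        len(records) - n_censored,
    )
    return out


def copies_per_reaction_to_per_ml(
    copies_per_reaction: float,
    reaction_template_volume_ml: float = DEFAULT_TEMPLATE_VOLUME_EQ_ML,
) -> float:
    """Convert copies per reaction to copies per mL of sampled water.

    ``copies_per_ml = copies_per_reaction / reaction_template_volume_ml``,
    where the volume factor is the mL-equivalents of filtered water whose
    extract ends up in one reaction.
    """
    if reaction_template_volume_ml <= 0:
        raise ValidationError("reaction_template_volume_ml must be > 0")
    return copies_per_reaction / reaction_template_volume_ml


def detection_limit_copies_per_ml(
    curve: StandardCurve,
    threshold_cq: float = DEFAULT_CQ_THRESHOLD,
    reaction_template_volume_ml: float = DEFAULT_TEMPLATE_VOLUME_EQ_ML,
) -> float:
    """Concentration corresponding to the Cq censoring threshold."""
    copies = cq_to_copies(threshold_cq, curve)
    assert copies is not None
    return copies_per_reaction_to_per_ml(copies, reaction_template_volume_ml)
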