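"""Threshold decision tree mapping lesion features to a Breslow category.

The tree first splits on circularity: irregular lesions (circularity below
the threshold, default 0.75) are resolved by their mean green-channel
intensity, while compact lesions (circularity at or above the threshold)
are resolved by their mean infrared intensity.  Deeper tumors absorb more
in the infrared, so low IR intensity on the compact branch indicates a
thick (> 2 mm) melanoma.

Tie handling is frozen by tests: "over / higher" branches are closed
(``>=`` the threshold), "under / lower" branches are open (``<``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ConfigurationError, InputError
from .features import FeatureVector


class BreslowCategory(enum.IntEnum):
    """Ordinal clinical Breslow-thickness category."""

    LT1 = 0  # < 1 mm
    MID = 1  # 1-2 mm (boundaries inclusive)
    GT2 = 2  # > 2 mm

    @property
    def label(self) -> str:
        return _LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "BreslowCategory":
        try:
            return _FROM_LABEL[label.strip()]
        except KeyError:
            raise InputError(f"unknown Breslow category label: {label!r}") from None


_LABELS = {BreslowCategory.LT1: "<1", BreslowCategory.MID: "1-2", BreslowCategory.GT2: ">2"}
_FROM_LABEL = {v: k for k, v in _LABELS.items()}

CATEGORIES = (BreslowCategory.LT1, BreslowCategory.MID, BreslowCategory.GT2)


@dataclass(frozen=True)
class ThresholdConfig:
    """Decision-tree thresholds, in the units of the extracted features.

    Intensity thresholds are on the 8-bit (0-255 A.U.) scale of the input
    images; they are configurable because the acquisition scale of the
    original device is not standardized.
    """

    circularity_threshold: float = 0.75
    g_threshold: float = 8.0
    ir_threshold: float = 113.7

    def __post_init__(self) -> None:
        if not 0.0 < self.circularity_threshold <= 1.0:
            raise ConfigurationError(
                f"circularity_threshold must be in (0, 1], got {self.circularity_threshold}"
            )
        for name in ("g_threshold", "ir_threshold"):
            value = getattr(self, name)
            if not 0.0 <= value <= 255.0:
                raise ConfigurationError(f"{name} must be in [0, 255], got {value}")


def classify_msi(
    features: FeatureVector, cfg: ThresholdConfig = ThresholdConfig()
) -> BreslowCategory:
    """Classify one lesion from its multispectral features.

    Total function: every feature vector maps to exactly one category.
    Only circularity, mean_G and mean_IR participate; solidity, roundness
    and mean_R are measured but deliberately unused by the tree.
    """
    if features.circularity < cfg.circularity_threshold:
        if features.mean_G >= cfg.g_threshold:
            return BreslowCategory.LT1
        return BreslowCategory.MID
    if features.mean_IR < cfg.ir_threshold:
        return BreslowCategory.GT2
    return BreslowCategory.MID


def categorize_thickness(thickness_mm: float) -> BreslowCategory:
    """Bin a continuous thickness (histological or ultrasound) into the
    three clinical categories; 1 mm and 2 mm fall in the middle bin."""
    if not thickness_mm > 0:
        raise InputError(f"thickness must be positive, got {thickness_mm}")
    if thickness_mm < 1.0:
        return BreslowCategory.LT1
    if thickness_mm <= 2.0:
        return BreslowCategory.MID
    return BreslowCategory.GT2
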