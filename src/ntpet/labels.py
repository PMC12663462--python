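"""Default organ label dictionary for the digital phantom.

Integer codes are arbitrary but stable; organ names are the interface.  The
set covers the tissues analysed in the twin correction (subcutaneous fat,
visceral fat, skeletal muscle, liver, aorta) plus the high-variation organs
excluded from anomaly segmentation (kidneys, heart, bladder, brain,
intestines) and bone.
"""

from __future__ import annotations

BACKGROUND = 0

DEFAULT_LABELS: dict[str, int] = {
    "subcutaneous_fat": 1,
    "visceral_fat": 2,
    "skeletal_muscle": 3,
    "liver": 4,
    "aorta": 5,
    "kidneys": 6,
    "heart": 7,
    "bladder": 8,
    "brain": 9,
    "small_intestine": 10,
    "large_intestine": 11,
    "bone": 12,
}

#: Organs with highly variable physiological uptake, ignored by default when
#: segmenting anomaly maps.
DEFAULT_EXCLUDED_ORGANS: tuple[str, ...] = (
    "kidneys",
    "heart",
    "bladder",
    "brain",
    "small_intestine",
    "large_intestine",
)

#: The organs analysed in the twin-correction battery.
ANALYSIS_ORGANS: tuple[str, ...] = (
    "subcutaneous_fat",
    "visceral_fat",
    "skeletal_muscle",
    "liver",
    "aorta",
)


def invert(labels: dict[str, int]) -> dict[int, str]:
    return {v: k for k, v in labels.items()}
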