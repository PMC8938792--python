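"""Sinonasal region vocabulary shared across the package.

Twelve scored regions: the five paired paranasal sinuses (maxillary,
anterior ethmoid, posterior ethmoid, frontal, sphenoid) plus the paired
ostiomeatal complex (OMC).  Class 0 is background; classes 1-12 follow
REGION_IDS order.
"""

from __future__ import annotations

REGION_IDS: tuple[str, ...] = (
    "Max-L", "Max-R",
    "AE-L", "AE-R",
    "PE-L", "PE-R",
    "Fro-L", "Fro-R",
    "Sph-L", "Sph-R",
    "OMC-L", "OMC-R",
)

SINUS_IDS: tuple[str, ...] = tuple(r for r in REGION_IDS if not r.startswith("OMC"))
OMC_IDS: tuple[str, ...] = ("OMC-L", "OMC-R")

N_REGIONS = len(REGION_IDS)
N_CLASSES = N_REGIONS + 1  # + background

REGION_TO_CLASS: dict[str, int] = {r: i + 1 for i, r in enumerate(REGION_IDS)}
CLASS_TO_REGION: dict[int, str] = {v: k for k, v in REGION_TO_CLASS.items()}


def region_class(region_id: str) -> int:
    try:
        return REGION_TO_CLASS[region_id]
    except KeyError:
        raise KeyError(
            f"unknown region {region_id!r}; expected one of {REGION_IDS}"
        ) from None
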