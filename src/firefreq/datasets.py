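"""Published fire-regime parameter estimates for Jalapão State Park (Cerrado).

Discrete lognormal parameters and summary statistics estimated from the
1997-2008 Landsat burned-area record of Jalapão State Park, Tocantins,
Brazil, for the seven major land-cover physiognomies.  These serve as
verification anchors and as realistic generating parameters for the
landscape simulator; the underlying imagery is not required.

Fields per class: area in hectares, percent of the park, fire rotation
period (years), annual percent area burned, (mu, sigma) of the discrete
lognormal interval model, and the published Hollander-Proschan
goodness-of-fit statistic with its p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import DiscreteLognormalParams

__all__ = ["LandCoverClass", "JALAPAO_CLASSES", "JALAPAO_YEARS", "UNBURNABLE_HA"]


@dataclass(frozen=True)
class LandCoverClass:
    code: str
    name: str
    area_ha: float
    area_pct: float
    frp: float
    apab: float
    params: DiscreteLognormalParams
    hp_stat: float
    hp_p: float


JALAPAO_YEARS = (1997, 2008)  # inclusive 12-year record

# Sand (511 ha) and water (250 ha) are unburnable and excluded from the
# area susceptible to burn.
UNBURNABLE_HA = {"sand": 511.0, "water": 250.0}

JALAPAO_CLASSES: dict[str, LandCoverClass] = {
    c.code: c
    for c in [
        LandCoverClass("SS", "Shrub Savanna", 93680, 58.9, 2.72, 37, DiscreteLognormalParams(0.82, 0.66), -1.24, 0.21),
        LandCoverClass("OW", "Open Woodland", 29310, 18.4, 2.75, 36, DiscreteLognormalParams(0.93, 0.69), -1.07, 0.29),
        LandCoverClass("DW", "Dense Woodland", 11008, 6.9, 5.49, 18, DiscreteLognormalParams(1.78, 0.99), -0.90, 0.37),
        LandCoverClass("VR", "Vereda", 8794, 5.5, 3.02, 33, DiscreteLognormalParams(0.90, 0.80), -1.03, 0.31),
        LandCoverClass("GF", "Gallery Forest", 13459, 8.5, 4.44, 23, DiscreteLognormalParams(1.19, 0.91), -0.85, 0.40),
        LandCoverClass("CF", "Cilliary Forest", 908, 0.6, 4.57, 22, DiscreteLognormalParams(1.39, 0.92), -0.95, 0.35),
        LandCoverClass("SC", "Shift Cultivation", 1233, 0.8, 3.71, 27, DiscreteLognormalParams(0.86, 0.89), -0.92, 0.36),
    ]
}
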