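"""Shared configuration for the analysis drivers.

The synthetic landscape emulates the statistical structure of the Jalapão
State Park burned-area record: seven land-cover classes in their published
area shares, each burning as a discrete-renewal process with its published
lognormal interval parameters, observed through a 12-year window with
start/end censoring.
"""

from pathlib import Path

from firefreq import ClassSpec, SimulationConfig
from firefreq.datasets import JALAPAO_CLASSES

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def jalapao_like_config(shape=(260, 260), cell_size=500.0, seed=0) -> SimulationConfig:
    """Seven-class landscape in the published area shares.

    At 260x260 cells of 500 m the landscape holds ~169,000 ha, matching the
    order of magnitude of the park's burnable area; the 500 m cell size
    equals the sampling grid spacing so each cell is one sample point.
    """
    total = sum(c.area_ha for c in JALAPAO_CLASSES.values())
    classes = [ClassSpec(c.code, c.params, c.area_ha / total) for c in JALAPAO_CLASSES.values()]
    return SimulationConfig(
        classes=classes,
        shape=shape,
        cell_size=cell_size,
        years=(1997, 2008),
        burn_in=50,
        t_max=150,
        seed=seed,
    )
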