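"""Fire-regime descriptors implied by the published interval-model fits.

Takes the published (mu, sigma) per land-cover class, evaluates the
discrete lognormal interval, survival and hazard-of-burning curves, and
tabulates median, mode, hazard turning point and peak hazard.  Writes
results/published_descriptors.csv and per-class curve CSVs.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS

from firefreq import derived_descriptors, hazard
from firefreq.datasets import JALAPAO_CLASSES
from firefreq.report import distribution_curves


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for code, c in JALAPAO_CLASSES.items():
        median, mode, tp = derived_descriptors(c.params)
        peak = float(np.max(hazard(np.arange(1, 101), c.params)))
        rows.append(
            dict(
                class_code=code,
                name=c.name,
                mu=c.params.mu,
                sigma=c.params.sigma,
                median=median,
                mode=mode,
                turning_point=tp,
                peak_hazard=round(peak, 4),
                frp_published=c.frp,
                apab_published=c.apab,
            )
        )
        curves = distribution_curves(c.params, t_max=30)
        curves.to_csv(RESULTS / f"curves_{code}.csv", index=False)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "published_descriptors.csv", index=False)
    print(df.to_string(index=False))
    print(
        "\nMedian intervals span 3 (shrub savanna) to 6 years (dense woodland); "
        "every class has a turning point of 3-4 years, so the hazard of burning "
        "rises for the first few fuel-age years and declines afterwards."
    )


if __name__ == "__main__":
    main()
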