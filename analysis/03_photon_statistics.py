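"""Photon-budget limits of the barycenter lifetime estimator.

Renders uniform bilayers at 25-1600 photons/pixel, measures the per-pixel
lifetime spread and verifies the expected N^(-1/2) shot-noise scaling and
the photon/lifetime validity cutoffs.  Writes results/photon_statistics.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from mtflim.experiments import lifetime_photon_scaling
from mtflim.flim import lifetime_precision

OUT = Path("results")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    res = lifetime_photon_scaling(seed=SEED)
    rows = [
        {
            "photons_per_pixel": n,
            "shot_noise_lower_bound_ns": lifetime_precision(n, 0.72),
        }
        for n in res["photon_levels"]
    ]
    df = pd.DataFrame(rows)
    df["loglog_slope"] = res["slope"]
    df.to_csv(OUT / "photon_statistics.csv", index=False, float_format="%.6g")
    print(
        f"lifetime spread scales with slope {res['slope']:.3f} "
        "(shot-noise expectation -0.5); validity mask applied exactly: "
        f"{res['mask_exact']}"
    )


if __name__ == "__main__":
    main()
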