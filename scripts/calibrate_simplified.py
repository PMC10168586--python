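"""Regenerate the frozen Simplified-Model calibration.

Measures the Complete Model's reference rates, rate-matches the auxiliary
populations, tunes the real populations' I_e offsets at epsilon = 0, and
writes the result to src/bgbeta/data/simplified_model.yaml.

Run from the repository root:  python scripts/calibrate_simplified.py
"""

import sys
import time

import numpy as np
import yaml

from bgbeta import ModelConfig, build_complete_model, run_simulation
from bgbeta.builders import calibrate_simplified


def main(seed: int = 0) -> None:
    t0 = time.time()
    rates = {nm: [] for nm in ("D2", "FSN", "GPTI", "STN")}
    for si in (0, 1):
        net = build_complete_model(ModelConfig(variant="complete", seed=seed + si))
        raster = run_simulation(net, duration=5000.0, warmup=500.0, seed=seed + si)
        for nm in rates:
            rates[nm].append(raster.mean_rate(nm))
    targets = {nm: float(np.mean(v)) for nm, v in rates.items()}
    print("complete-model reference rates:", targets, flush=True)

    cal = calibrate_simplified(targets, epsilon=0.0, seed=seed)
    print("calibration:", cal, flush=True)

    header = open("src/bgbeta/data/simplified_model.yaml").read().split("version:")[0]
    with open("src/bgbeta/data/simplified_model.yaml", "w") as fh:
        fh.write(header)
        yaml.safe_dump(cal, fh, sort_keys=True)
    print(f"written ({time.time() - t0:.0f} s)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
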