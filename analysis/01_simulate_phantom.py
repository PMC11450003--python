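"""Forward acoustic simulation of the ink-channel phantom.

Propagates the photoacoustic wave from a 2 mm channel centred 7 mm deep
in a 12 mm PDMS slab to the detection surface and measures the
Hilbert-envelope arrival time of the surface velocity, for (a) an
idealised uniform initial pressure across the channel and (b) the
physical backside-illuminated Beer-Lambert deposition at 1 % ink.

Finding: the uniform disc produces two nearly equal envelope lobes (near
and far channel edge) and its envelope peak sits at the near-edge
arrival ~6 us, whereas the backside-illuminated crescent source arrives
through the faster water channel at ~7.2 us — matching the ~7 us delay
seen on the real sample.

Writes results/arrival_times.csv.
"""

import csv
from pathlib import Path

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from ldvpa import synthetic_data as sd
from ldvpa import wave_engine as we

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    phantom = sd.PhantomSpec(
        thickness=12e-3, channels=[sd.Channel(depth=7e-3)], ink_concentration=1.0
    )
    medium = we.build_medium(phantom, dx=20e-6, width=8e-3)
    sos = butter(4, 5e6, fs=65e6, output="sos")
    rows = []
    for illumination in ("uniform", "backside"):
        p0 = sd.initial_pressure_from_absorption(
            phantom, medium, fluence_scale=40.0, illumination=illumination
        )
        rec = we.simulate_forward(medium, p0, 10e-6, [0.0], fs_out=65e6)
        env = np.abs(hilbert(sosfiltfilt(sos, rec.velocity[0])))
        onset = rec.time[np.argmax(env > 0.2 * env.max())]
        peak = rec.time[np.argmax(env)]
        rows.append(
            {
                "illumination": illumination,
                "onset_us": round(onset * 1e6, 3),
                "envelope_peak_us": round(peak * 1e6, 3),
                "peak_velocity_mm_per_s": round(np.abs(rec.velocity[0]).max() * 1e3, 3),
            }
        )
        print(
            f"{illumination:9s}: onset {onset * 1e6:.2f} us, "
            f"envelope peak {peak * 1e6:.2f} us"
        )
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "arrival_times.csv", "w", newline="") as f:
        w = csv.DictWriter(f, fieldnames=rows[0].keys())
        w.writeheader()
        w.writerows(rows)
    print(f"wrote {RESULTS / 'arrival_times.csv'}")


if __name__ == "__main__":
    main()
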