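#!/usr/bin/env python
"""Compute the pupillary unrest index for alert vs drowsy synthetic traces.

Simulates two 11-minute dark-adapted pupil recordings — an alert subject
(large stable pupil) and a drowsy one (smaller pupil, high-amplitude slow
oscillations) — runs artifact preprocessing and the segmented PUI
computation, and writes both results to results/pui.json.
"""

import json
from pathlib import Path

from tva_arousal.io import pui_result_to_dict
from tva_arousal.pupillometry import compute_pui, preprocess_trace
from tva_arousal.synthetic_data import simulate_pupil_trace

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 3

PROFILES = {
    "alert": dict(base_pd_mm=7.4, oscillation_amplitude_mm=0.08,
                  oscillation_freq_hz=0.08, blink_rate_per_min=3.0),
    "drowsy": dict(base_pd_mm=6.3, oscillation_amplitude_mm=0.35,
                   oscillation_freq_hz=0.12, blink_rate_per_min=6.0,
                   long_dropout_prob=1.0),
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    out = {}
    for name, kwargs in PROFILES.items():
        trace = simulate_pupil_trace(seed=SEED, **kwargs)
        res = compute_pui(preprocess_trace(trace))
        out[name] = pui_result_to_dict(res)
        print(
            f"{name:>6}: PUI {res.total_pui:5.2f} mm/min  PD {res.mean_pd:.2f} mm  "
            f"segments used {res.n_segments_used}/8  "
            f"interpolated {res.n_samples_interpolated} samples"
        )
    (OUT / "pui.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"wrote {OUT / 'pui.json'}")


if __name__ == "__main__":
    main()
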