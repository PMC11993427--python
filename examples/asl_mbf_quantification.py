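"""Quantify myocardial blood flow from simulated FAIR-ASL series.

Simulates one reference (307 ms acquisition window) and one accelerated
(SENSE 2, 153 ms) series from the same underlying motion and noise
realisation, quantifies global/regional/septal MBF with the Buxton model,
and decomposes the temporal noise into physiological and thermal parts.
"""

from cardioquant.asl_quant import mbf_segments
from cardioquant.asl_sim import (
    ASLProtocol,
    ASLTruth,
    acquisition_window,
    simulate_series,
    total_window,
)

truth = ASLTruth(mbf_true=1.20, seed=42)  # ml/g/min

for name, sense in (("reference", 1), ("accelerated (SENSE 2)", 2)):
    protocol = ASLProtocol(sense_factor=sense)
    series = simulate_series(protocol, truth)
    result = mbf_segments(series)
    print(f"{name}: acquisition window {acquisition_window(protocol)} ms, "
          f"total imaging window {total_window(protocol):.0f} ms")
    print(f"  global MBF {result.global_mbf:.2f} ml/g/min "
          f"(true {truth.mbf_true:.2f})")
    print(f"  regional MBF (6 segments): "
          + " ".join(f"{v:.2f}" for v in result.regional_mbf))
    print(f"  septal MBF (3 segments):   "
          + " ".join(f"{v:.2f}" for v in result.septal_mbf))
    print(f"  physiological noise {result.pn:.3f}, "
          f"thermal noise {result.tn:.3f} ml/g/min\n")
# Shortening the acquisition window reduces motion-induced control/tag
# inconsistency, so PN drops under acceleration while TN rises slightly
# (sqrt(2) g-factor-style inflation) -- the trade that motivates SENSE here.
# Single-breath-hold regional segments are noise-dominated (values can even
# go negative); the narrow pi/3 filter trades precision for localisation,
# which is why global MBF uses the full-circle 2*pi filter.
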