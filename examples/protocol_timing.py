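"""Derive the acquisition timings of both imaging protocols.

The 4D-flow temporal resolution follows from the repetition time, the
k-space segmentation factor and the four acquisitions per line needed for
three-directional velocity encoding; the ASL windows follow from the
matrix size, TR, SENSE factor and the fat-sat/ramp overhead.
"""

from cardioquant.asl_sim import ASLProtocol, acquisition_window, total_window
from cardioquant.timing import FlowSequenceParams, kspace_acq_time, temporal_resolution

flow = FlowSequenceParams(tr=6.3, k_seg=2, n_encodes=4)
print(f"4D flow temporal resolution: {temporal_resolution(flow):.1f} ms "
      f"(4 encodes x k_seg 2 x TR 6.3 ms)")
cov = kspace_acq_time(n_lines=96, lines_per_cycle=16)
print(f"k-space coverage: {cov['cycles_needed']} heartbeats for "
      f"{cov['n_lines']} lines at {cov['lines_per_cycle']}/cycle")

for name, sense in (("reference", 1), ("accelerated", 2)):
    p = ASLProtocol(sense_factor=sense)
    print(f"ASL {name:11s}: acquisition window {acquisition_window(p):3d} ms, "
          f"total imaging window {total_window(p):.0f} ms")
# The accelerated protocol halves the acquired k-space lines, halving the
# per-cycle readout during which cardiac motion can corrupt the snapshot.
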