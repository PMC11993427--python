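"""Cohort table and paired method comparison on simulated subjects.

Simulates ten subjects, each scanned with the reference and the
accelerated ASL protocol under the same motion/noise realisation, then
prints mean +/- SD per metric and a paired t-test on global MBF.
"""

from cardioquant.asl_quant import mbf_segments
from cardioquant.asl_sim import ASLProtocol, ASLTruth, simulate_series
from cardioquant.report import compare_paired, summarize_cohort

ref_results, acc_results = [], []
for subject in range(10):
    truth = ASLTruth(mbf_true=1.20, seed=1000 + subject)
    ref_results.append(mbf_segments(simulate_series(ASLProtocol(sense_factor=1), truth)))
    acc_results.append(mbf_segments(simulate_series(ASLProtocol(sense_factor=2), truth)))

print("reference protocol (n = 10):")
print(summarize_cohort(ref_results).round(4).to_string())
print("\naccelerated protocol (n = 10):")
print(summarize_cohort(acc_results).round(4).to_string())

cmp_mbf = compare_paired(
    [r.global_mbf for r in ref_results], [r.global_mbf for r in acc_results]
)
cmp_pn = compare_paired([r.pn for r in ref_results], [r.pn for r in acc_results])
print(f"\npaired t-test, global MBF ref vs acc: mean diff "
      f"{cmp_mbf['mean_diff']:+.3f} ml/g/min, p = {cmp_mbf['p']:.3f}")
print(f"paired t-test, PN ref vs acc:        mean diff "
      f"{cmp_pn['mean_diff']:+.3f} ml/g/min, p = {cmp_pn['p']:.4f}")
# A non-significant MBF difference with a significant PN drop is the
# expected signature: acceleration preserves the flow estimate while
# suppressing motion-driven temporal noise.
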