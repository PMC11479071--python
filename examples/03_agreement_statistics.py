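"""Method-comparison statistics over a synthetic evaluation study.

Draws a 102-evaluation study table (paired radar/reference HRV indices
with realistic between-method noise), applies the validity screen, and
prints Pearson r, Bland-Altman bias and limits of agreement, and
ICC(2,1) per index.
"""

from pulsebeam import StudyParams, agreement_report, apply_outlier_rules, generate_study

study = generate_study(StudyParams(seed=3))
study = apply_outlier_rules(study)
print(f"{int(study['valid'].sum())}/{len(study)} evaluations pass the validity screen")
print("(screen: radar RMSSD <= 100 ms and radar SDNN inside the reference range)\n")

report = agreement_report(study)
print(f"{'index':12s} {'r':>8s} {'bias':>8s} {'LoA':>18s} {'ICC(2,1)':>9s} {'95% CI':>16s}")
for name, s in report.items():
    print(f"{name:12s} {s.pearson_r:8.4f} {s.bias:8.2f} "
          f"[{s.loa_low:7.2f}, {s.loa_high:6.2f}] {s.icc:9.4f} "
          f"[{s.icc_ci_low:6.3f}, {s.icc_ci_high:5.3f}]")

print("\nmean RR agrees near-perfectly (r and ICC > 0.999); RMSSD carries the")
print("largest between-method noise, so its ICC is the weakest — the ordering")
print("a radar-vs-ECG comparison typically shows.")
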