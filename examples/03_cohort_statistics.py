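"""Group-level rate statistics on a simulated two-cohort study.

Simulates a patient-like group with elevated left-temporal ripple rates and
a control group (rate-level simulation: ground-truth manifests only), builds
per-channel rate tables, and runs the regional machinery: channel-wise group
comparison with the normality-gated test selection, cross-region Spearman
summary, and the hemispheric asymmetry index with its group tests.
"""

import meghfo as m

layout = m.default_layout()

groups = (
    m.GroupSpec("patient", 10, {
        "TL": {"ripple": 400.0, "fast_ripple": 60.0},
        "TR": {"ripple": 200.0, "fast_ripple": 60.0},
        "OL": {"ripple": 150.0}, "OR": {"ripple": 150.0},
    }),
    m.GroupSpec("control", 10, {
        "TL": {"ripple": 200.0, "fast_ripple": 30.0},
        "TR": {"ripple": 200.0, "fast_ripple": 30.0},
        "OL": {"ripple": 150.0}, "OR": {"ripple": 150.0},
    }),
)
spec = m.CohortSpec(groups=groups, duration_s=600.0, seed=4)
subjects = m.make_cohort(spec, layout, synthesize_signal=False)

tables, assignment = [], {}
for s in subjects:
    events = [
        m.CandidateEvent(i.channel_label, i.onset_s, i.offset_s,
                         i.onset_s + i.duration_s / 2, i.peak_freq_hz,
                         25.0, 1.0, cls, i.n_cycles)
        for i, cls in s.manifest.events
    ]
    tables.append(m.compute_rates(events, layout, 10.0,
                                  subject_id=s.subject_id))
    assignment[s.subject_id] = s.group_name

matrix = m.channelwise_group_matrix(tables, assignment)
for r in m.compare_regions(matrix, regions=["TL", "TR"], classes=["ripple"]):
    means = ", ".join(f"{g}={v:.3f}" for g, v in r.group_means.items())
    print(f"{r.region} ripple: {r.test_used:12s} stat={r.statistic:7.2f} "
          f"p={r.p_value:.2e}  ({means} events/min)")
# TL (rates 400 vs 200 per 10 min) should be strongly significant;
# TR (200 vs 200) should not.

_, summary = m.cross_region_spearman(tables)
print("\ncross-region Spearman summary (median rho and IQR per class):")
print(summary.to_string(index=False))

ai = m.asymmetry_table(tables, region_pairs=["T"], classes=["ripple"])
ai_by_group = {
    g: ai[ai.subject_id.isin([s for s, gg in assignment.items() if gg == g])]
    ["ai"].dropna().to_numpy()
    for g in ("patient", "control")
}
print("\ntemporal asymmetry index (left-positive, range -200..200):")
for r in m.test_asymmetry(ai_by_group, "T", "ripple"):
    print(f"  {'/'.join(r.groups):18s} {r.test_used:12s} "
          f"stat={r.statistic:6.2f} p={r.p_value:.3f}")
# Patients were built with a 2:1 left:right temporal rate ratio, so their
# one-sample t against zero is significant; controls are symmetric.
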