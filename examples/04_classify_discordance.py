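"""Classify disease-like subjects and tabulate method discordance.

Builds both atlases from a synthetic normal cohort, classifies subjects
with atrophy injected in the temporal and hippocampal labels, and reports
where the two statistical methods disagree about abnormality — per subject
and per region.
"""

from normatlas import (
    CohortSpec,
    build_atlas,
    classify_subject,
    discordance,
    generate_atrophied_subjects,
    generate_normal_cohort,
    summarize_discordance,
)

spec = CohortSpec(shape=(20, 20, 20), n_normal=98, n_atrophied=10, seed=5)
synth = generate_normal_cohort(spec)
atrophied = generate_atrophied_subjects(spec)

par = build_atlas(synth.cohort, "parametric")
nonpar = build_atlas(synth.cohort, "nonparametric")

cats, ids = [], []
for i in range(atrophied.cohort.n_subjects):
    sid = atrophied.cohort.subject_ids[i]
    subject = atrophied.cohort.subject(i)
    c_p = classify_subject(subject, par, sid)
    c_np = classify_subject(subject, nonpar, sid)
    cats.append(discordance(c_p, c_np))
    ids.append(sid)

report = summarize_discordance(cats, ids, labels=synth.labels,
                               mask=synth.cohort.mask)
print("per-cohort discordance percentages (median, IQR over subjects):")
print(report.summary.to_string(float_format=lambda v: f"{v:.1f}"))
print("\nwhere the discordant voxels fall (proportion per region, pooled):")
print(report.per_region.to_string(float_format=lambda v: f"{v:.2f}"))
print("\npct_normalP_abnormalNP: of voxels the order-based atlas flags, the "
      "share the mean±SD atlas misses (its limit often sits below 0); "
      "pct_abnormalP_normalNP: the share the mean±SD atlas over-calls.")
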