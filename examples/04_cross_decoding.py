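"""Cross-condition value decoding from synthetic multivoxel patterns.

A ridge decoder (alpha=10^3) is trained on one trial type and tested on
held-out runs of both types. A shared value code generalizes across
conditions (all four splits decode); a condition-specific code (item and
bundle values on orthogonal directions) decodes only within condition.
"""

import bundleval as bv

catalog = bv.build_item_roster(seed=1)
spec = bv.GenerativeBundleSpec(family="divnorm", noise_sd=1.0)
wtp = bv.simulate_wtp_dataset(spec, catalog, n_subjects=1, seed=2)
schedule = bv.build_trial_schedule(catalog, wtp, seed=3)

for label, kwargs in [
    ("shared value code", {}),
    ("condition-specific code", {"separate_directions": True}),
]:
    scheme = bv.CodingScheme(scheme="zscore", noise_sd=1.5, n_voxels=100,
                             **kwargs)
    data = bv.simulate_voxel_patterns(schedule, wtp, scheme, seed=4,
                                      subject_id=1)
    res = bv.cross_decode(data)
    print(f"\n{label} (mean Pearson r across 15 folds):")
    for row in res.itertuples(index=False):
        print(f"  {row.split:~<32} r = {row.accuracy:+.3f}")
print("\ncross-condition generalization is the signature of a shared code;"
      "\nits absence would indicate distinct item and bundle value codes")
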