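"""Build the three-day experimental design and elicit synthetic WTP bids.

40 consumer items (half food, half trinkets), 20 per day with 10 shared
across days; every within-day pair plus each self-pair forms the day's 210
bundles. Bids come from a divisive-normalization value model on a $0-$20
budget, and a BDM auction makes truthful bidding optimal.
"""

import numpy as np

import bundleval as bv
from bundleval.synth import expected_bdm_surplus, simulate_bdm_outcome

catalog = bv.build_item_roster(40, 10, 10, 3, seed=1)
bundles = bv.enumerate_bundles(catalog.day_rosters[1], catalog)
print(f"items total: {catalog.n_items}, per day: {len(catalog.day_rosters[1])}")
print(f"bundles per day: {len(bundles)} "
      f"({sum(b.left_item != b.right_item for b in bundles)} pairs + "
      f"{sum(b.left_item == b.right_item for b in bundles)} self-pairs)")

spec = bv.GenerativeBundleSpec(family="divnorm", noise_sd=1.0)
wtp = bv.simulate_wtp_dataset(spec, catalog, n_subjects=2, seed=2)
item_ref, bundle_ref = bv.compute_reference_amounts(wtp, subject_id=1, day=1)
print(f"subject 1, day 1 median bids — items: ${item_ref:.2f}, "
      f"bundles: ${bundle_ref:.2f}  (the choice-task reference amounts)")

# BDM: expected surplus is maximized by bidding the true value
grid = np.arange(0, 20.01, 0.25)
true_value = 8.0
best_bid = grid[np.argmax([expected_bdm_surplus(b, true_value) for b in grid])]
print(f"BDM: true value ${true_value:.0f} -> optimal bid ${best_bid:.2f} "
      "(truthful bidding)")
purchased, paid = simulate_bdm_outcome(8.0, seed=3)
print(f"one auction draw at bid $8: purchased={purchased}, paid=${paid:.2f}")
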