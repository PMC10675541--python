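"""Partition a dataset into molecular-weight bands and split train/test.

Generates a small synthetic dataset, bins the molecules into the seven
50-amu bands spanning 250-600 amu, splits each band 4:1 and picks the
band's heaviest member as the alignment template.
"""

from espqsar.chemio import partition_by_mw, select_template, split_train_test
from espqsar.synthdata import SyntheticSpec, make_benchmark

dataset = make_benchmark(SyntheticSpec(members_per_subset=10, seed=42))
print(f"dataset: {len(dataset.molecules)} molecules, "
      f"MW {dataset.activities.mw.min():.0f}-{dataset.activities.mw.max():.0f} amu, "
      f"pIC50 {dataset.activities.pic50.min():.2f}-{dataset.activities.pic50.max():.2f}")

for subset in partition_by_mw(dataset.molecules):
    split = split_train_test(subset, ratio=(4, 1), seed=7)
    template = select_template(split, dataset.molecules)
    lo, hi = subset.mw_range
    print(f"band {subset.subset_index} ({lo:.0f}, {hi:.0f}] amu: "
          f"{len(split.train_ids())} train / {len(split.test_ids())} test, "
          f"template {template.id} ({template.mw:.1f} amu)")

# Each band holds molecules of similar size; the heaviest member anchors
# the pairwise field alignment of everything else in the band.
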