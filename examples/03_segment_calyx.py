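"""Segment tomato vs calyx-stem tissue and score the masks against ground truth.

The segmentation normalizes each pixel's spectrum (SNV), filters it with the
first derivative of a Gaussian (sigma_g = 2.5 band steps), sums the absolute
responses below / above the 1150 nm split into two significance maps, and
Otsu-thresholds each map.  Dice overlap against the generator's true masks
measures recovery.
"""

import sepalnir as sn

cube, refs, truth = sn.generate_scene(sn.SceneConfig(seed=7))
result = sn.process_scene(cube, refs, truth.sepal_labels)

d_tomato = sn.dice_score(result.masks.tomato, truth.tomato_mask)
d_calyx = sn.dice_score(result.masks.calyxstem, truth.calyxstem_mask)
print(f"Dice tomato:     {d_tomato:.3f}")
print(f"Dice calyx-stem: {d_calyx:.3f}")
print(f"sepals extracted: {len(result.records)} "
      f"(mean area {sum(r.pixel_count for r in result.records) / len(result.records):.0f} px)")
print("-> Dice near 1.0 means the automatic masks almost coincide with the")
print("   drawn ground truth; sepal records carry one mean and one sd spectrum each.")
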