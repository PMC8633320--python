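"""Generate one synthetic truss scene and inspect its structure.

Builds a raw NIR cube (224 bands, 900-1671 nm) of two trusses of cocktail
tomatoes with sepal fans, plus white/black references and ground-truth masks,
then verifies the statistical contrast the segmentation relies on: tomato
tissue varies mostly below 1150 nm, sepal tissue mostly above.
"""

import numpy as np

import sepalnir as sn

cfg = sn.SceneConfig(seed=7)
cube, refs, truth = sn.generate_scene(cfg)

print(f"cube: {cube.data.shape[0]}x{cube.data.shape[1]} px, {cube.n_bands} bands "
      f"({cube.wavelengths[0]:.0f}-{cube.wavelengths[-1]:.0f} nm)")
print(f"sepals: {len(truth.sepal_table)} across {cfg.n_trusses} trusses "
      f"of {cfg.tomatoes_per_truss} tomatoes")

refl = sn.flat_field_correct(cube, refs)
low = refl.wavelengths < 1150
high = ~low
var_tomato = refl.data[truth.tomato_mask].var(axis=0)
var_sepal = refl.data[truth.calyxstem_mask].var(axis=0)
print(f"across-pixel variance below 1150 nm: tomato {var_tomato[low].mean():.4f} "
      f"vs sepal {var_sepal[low].mean():.4f}")
print(f"across-pixel variance above 1150 nm: tomato {var_tomato[high].mean():.4f} "
      f"vs sepal {var_sepal[high].mean():.4f}")
print("-> the variance ordering flips at 1150 nm, which is what lets the")
print("   derivative-significance maps separate the two tissue classes.")
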