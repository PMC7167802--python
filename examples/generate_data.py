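"""Generate both synthetic dataset styles and inspect their statistics.

EM-like tiles: grayscale textures partitioned into cells by dark 1-3 px
membranes, with binary in-out masks.  BRATs-like slices: 4 modality
surrogate channels with nested 4-class tumor labels.  Everything is a
pure function of (parameters, seed).
"""

import numpy as np

from sdunet import generate_brats_like, generate_em_like
from sdunet.synthetic_data import expected_class_priors

em = generate_em_like(5, 64, 64, seed=42)
membrane = [1.0 - s.mask.mean() for s in em]
print(f"EM-like: {len(em)} tiles, image range "
      f"[{em[0].image.min():.2f}, {em[0].image.max():.2f}], "
      f"membrane fraction {np.mean(membrane):.3f} "
      f"({em[0].meta['n_cells']} cells per tile)")

br = generate_brats_like(100, 64, 64, seed=42)
counts = np.zeros(4)
for s in br:
    counts += np.bincount(s.mask.ravel(), minlength=4)
emp = counts / counts.sum()
exp = expected_class_priors()
print("BRATs-like class frequencies (empirical vs expected):")
for i, name in enumerate(["background", "edema", "enhancing",
                          "non-enhancing"]):
    print(f"  {name:14s} {emp[i]:.4f}  vs  {list(exp.values())[i]:.4f}")
small = sum(s.meta["small_tumor"] for s in br)
print(f"{small}/100 slices carry small tumors (<2% of pixels)")
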