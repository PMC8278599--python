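"""Generate a co-registered structural/functional phantom pair.

The structural image mimics an MR slice (bright skull ring, textured
cortex, dark ventricles); the functional image mimics a SPECT/PET slice
(smooth hot-iron activity blobs on the same brain mask).
"""

from pathlib import Path

import hahnfusion as hf

out = Path(__file__).parent / "output"
out.mkdir(exist_ok=True)

pair = hf.make_pair(size=256, seed=42)
hf.save_image(pair.structural, out / "structural.png")
hf.save_image(pair.functional, out / "functional.png")

mask = hf.brain_mask(pair.size)
print(f"pair seed={pair.seed} size={pair.size} lesion={pair.lesion}")
print(f"structural: mean inside brain {pair.structural[mask].mean():.3f}, "
      f"outside {pair.structural[~mask].mean():.3f}")
print(f"functional: peak activity {pair.functional.max():.3f} "
      f"(0 outside the brain mask: {bool((pair.functional[~mask] == 0).all())})")
print(f"wrote {out / 'structural.png'} and {out / 'functional.png'}")
# Inside-vs-outside contrast shows the anatomy phantom has a real brain
# silhouette; the functional image shares it exactly (co-registration).
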