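"""Fuse three modalities (CT-like, MRI-like, PET-like) in one pass.

Feature maps are extracted per modality in parallel and compete block by
block, so adding a third input needs no cascaded pairwise fusion and no
choice of fusion order.
"""

from pathlib import Path

import numpy as np

import hahnfusion as hf

out = Path(__file__).parent / "output"
out.mkdir(exist_ok=True)

ct, mri, pet = hf.make_tri_modal(size=64, seed=5)
net = hf.build_network(seed=0)  # see 04_train_and_fuse.py to train first

res = hf.run_fusion(hf.FusionJob(inputs=(ct, mri, pet), network=net,
                                 output_path=out / "tri_fused.png",
                                 score=False))
print(f"mode={res.mode}, fused shape={res.fused.shape}")

# order independence: any permutation of the inputs gives the same image
res2 = hf.run_fusion(hf.FusionJob(inputs=(pet, ct, mri), network=net,
                                  score=False))
print("order-invariant:", bool(np.array_equal(res.fused, res2.fused)))
print(f"wrote {out / 'tri_fused.png'}")
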