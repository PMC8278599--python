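"""Train the autoencoder at desk scale and fuse a held-out phantom pair.

A few minutes on one CPU: 24 small phantoms, 12 epochs.  The fused image is
scored against both sources with the six-metric suite and compared with the
naive 50/50 pixel average.
"""

from pathlib import Path

import hahnfusion as hf
from hahnfusion.image_io import to_network_input

out = Path(__file__).parent / "output"
out.mkdir(exist_ok=True)

pairs = hf.make_dataset(13, size=64, seed=7)
train = ([to_network_input(p.structural) for p in pairs[:12]]
         + [p.functional for p in pairs[:12]])

net = hf.build_network(seed=0)
net, history = hf.train_autoencoder(
    net, train, hf.TrainConfig(epochs=12, batch_size=8, seed=0))
print(f"loss: epoch 0 = {history[0]:.4f} -> epoch {len(history)-1} = "
      f"{history[-1]:.4f}")

held = pairs[-1]
fused = hf.fuse_images([held.structural, held.functional], net)
hf.save_image(fused, out / "fused.png")

baseline = 0.5 * (to_network_input(held.structural) + held.functional)
for name, img in [("hahn-pcnn fused", fused), ("pixel average", baseline)]:
    rep = hf.score_all(hf.FusionTriplet(held.structural, held.functional,
                                        img))
    d = rep.as_dict()
    print(f"{name:16s} Qabf={d['qabf']:.3f} SSIM={d['ssim']:.3f} "
          f"VIF={d['vif']:.3f} FMI={d['fmi']:.3f} SF={d['sf']:.4f} "
          f"CE={d['ce']:.3f}")
# Higher Qabf/SSIM/VIF/FMI/SF and lower CE are better.  At desk scale the
# fused image wins clearly on CE (its histogram stays close to the
# sources') but loses edge scores to the average: with autoencoder-trained
# features the block energy tracks brightness, so selection favours the
# smooth bright functional source (see docs/methods.md, Known limitations).
# Pretrained edge-sensitive first-layer weights are the regime where
# block selection recovers texture instead.
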