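"""Look inside the network: attention rows and squeeze-excitation gates.

Runs one phantom through a freshly initialised full network and prints the
bottleneck attention statistics (each row of the 16x16 token-attention
matrix sums to one: every token distributes its attention across the 4x4
spatial grid) and the range of the squeeze-and-excitation channel gates
(strictly inside (0, 1): channels are softly re-weighted, never zeroed or
amplified unboundedly).
"""

import numpy as np

from mixerseg import ModelConfig, PhantomConfig, build_model, generate_phantoms
from mixerseg.blocks import SEBlock

phantom = generate_phantoms(PhantomConfig(n_images=1, seed=3, size=128, lesions_range=(1, 1)))[0]
x = phantom.image[None, :, :, None].astype(np.float32)

model = build_model(ModelConfig(input_size=128, width_mult=0.25, seed=0))
probs = model.forward(x, training=True)

attn = model.bottleneck.last_attention  # (batch, heads, tokens, tokens)
print(f"bottleneck token grid: {model.bottleneck_grid} -> {attn.shape[-1]} tokens")
print(f"attention heads: {attn.shape[1]}")
print(f"attention row sums (should all be 1): "
      f"min={attn.sum(-1).min():.6f} max={attn.sum(-1).max():.6f}")
print(f"most-attended token per head: {attn.mean(axis=2).argmax(axis=-1)[0]}")

gates = [layer.last_gates for layer in model.iter_layers() if isinstance(layer, SEBlock)]
lo = min(g.min() for g in gates)
hi = max(g.max() for g in gates)
print(f"\n{len(gates)} squeeze-excitation blocks; gate range across all: "
      f"({lo:.3f}, {hi:.3f})")
print(f"untrained output probabilities span ({probs.min():.3f}, {probs.max():.3f})")
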