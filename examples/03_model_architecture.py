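"""Inspect the four architectures: shape chains and parameter counts.

Prints the encoder/decoder shape chain of the supervised autoencoder with
the Bi-LSTM head for 2 s segments, and compares parameter counts across
all four variants.
"""

from sdcae import ModelConfig, build_model, infer_shapes
from sdcae.nn.models import VARIANTS

config = ModelConfig("DCAE_BiLSTM", duration_s=2)
print("DCAE_BiLSTM, 2 s segments:")
for name, shape in infer_shapes(config):
    print(f"  {name:20s} {shape}")

print("\nparameter counts (full scale / filters divided by 8):")
for variant in VARIANTS:
    full = build_model(ModelConfig(variant, duration_s=2), seed=0).n_params
    tiny = build_model(ModelConfig(variant, duration_s=2).tiny(8), seed=0).n_params
    print(f"  {variant:12s} {full:>9,d} / {tiny:>7,d}")
print("-> the encoder halves time 4x and collapses 24 channel columns to 1;")
print("   DCNN variants drop the decoder, so they are strictly smaller.")
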