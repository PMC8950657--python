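"""Encode one RNA window under all eleven feature schemes.

Shows the worked 'GAGACU' toy for the position-aware schemes and the feature
dimension each scheme produces on a full 41-nt window.
"""

import dhupred as dp
from dhupred import encoders as enc

print("worked example, seq = GAGACU")
print("  NCP    :", enc.encode_ncp("GAGACU").astype(int).tolist(),
      " (3 chemistry bits per base: ring, functional group, H-bond)")
print("  BINARY :", enc.encode_binary("GAGACU").astype(int).tolist(),
      " (one-hot per base, order A,G,C,U)")
print("  ANF    :", [round(float(v), 4) for v in enc.encode_anf("GAGACU")],
      " (prefix density of each base at its position)")
print("  NAC    :", [round(float(v), 4) for v in enc.encode_nac("GAGACU")],
      " (mononucleotide composition, order A,C,G,U)")

print("\nfeature dimensions for a 41-nt window:")
window = dp.generate_dataset(dp.SyntheticConfig(seed=1)).records[0].sequence
for name in dp.ENCODER_NAMES:
    spec = dp.EncoderSpec(name)
    vec = enc.encode_sequence(window, spec)
    print(f"  {name:8s} -> {vec.shape[0]:4d} features")
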