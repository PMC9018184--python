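"""Channel-order contract shared by the generator, discriminators and data.

Global (full-frame) conditioning stack, in order:
    x1 — preparation with adjacent teeth (depth levels / 255)
    c1 — opposing tooth depth map (levels / 255)
    c2 — biological-morphology mask: occlusal fingerprint ∪ occlusal groove
    d  — inter-jaw gap distance, clipped to [0, h] and divided by h

Local (defect-crop) stack, in order:
    x1p — preparation crop
    c1p — opposing crop
    c3  — occlusal-groove mask crop
    dp  — gap-distance crop

Discriminators see the conditioning stack with the (real or generated)
crown image appended as the last channel.
"""

GLOBAL_CHANNELS = ("x1", "c1", "c2", "d")
LOCAL_CHANNELS = ("x1p", "c1p", "c3", "dp")
N_COND_CHANNELS = len(GLOBAL_CHANNELS)
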