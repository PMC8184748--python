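# Default per-viewpoint blacklist and IGH region (hg19 coordinates).
# IGL probes show recurrent off-target calls at chr9:131.5-132.5 Mb and IGK
# probes at chr22:22-24 Mb (the IGL locus itself, attributable to IGK/IGL
# sequence similarity causing misalignment); calls there are removed for the
# owning viewpoint only. The IGH area is exempt from amplification detection
# because double/triple-hit lymphomas legitimately fuse several targets to it.
# Other genome builds require user-supplied coordinates.
blacklist:
  IGL:
    - [chr9, 131500000, 132500000]
  IGK:
    - [chr22, 22000000, 24000000]
igh_region: [chr14, 105500000, 107300000]
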