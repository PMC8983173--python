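# Regulatory-site map for the toy promoter amplicon. The label is symbolic;
# the coordinate is a 0-based column of the aligned amplicon block.
sites:
  NT-26:
    index: 133
    ref: G
    alt: T
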