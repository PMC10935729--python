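# Default structural alerts: one SMARTS per line, '#' comments allowed.
# Reactive / unstable groups and abnormal ring sizes commonly excluded from
# generative runs. Fully replaceable via the run configuration.
[*;r8]
[*;r9]
[*;r10]
[*;r11]
[*;r12]
[#8]-[#8]            # peroxide
[#16]-[#16]          # disulfide
[#7;!n]-[#7;!n]      # acyclic hydrazine
[#6](=[#8])[Cl,Br,I] # acyl halide
C=C=C                # allene
[O-][N+](=O)         # nitro
[C;H2]([Cl,Br,I])[Cl,Br,I]  # gem-dihalide
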