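# Canonical murine disease-associated microglia (DAM) marker panel.
# Curated from the widely used DAM signature literature (Trem2/Apoe-axis
# activation program); user-replaceable via DAMParams.markers or a GMT file.
Trem2
Cst7
Lpl
Itgax
Apoe
Clec7a
Tyrobp
Axl
Cd9
Spp1
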