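# Species never counted as biomass components: water, protons and
# inorganic ions in the BiGG namespace (cytosolic forms; add other
# compartment suffixes for models that draw biomass from elsewhere).
# The authoritative component list for a given published model is its own
# supplementary table; this default reproduces the common convention of
# keeping only organic substrates of the biomass reaction.
- h2o_c
- h_c
- nh4_c
- ca2_c
- cl_c
- cobalt2_c
- cu2_c
- fe2_c
- fe3_c
- k_c
- mg2_c
- mn2_c
- mobd_c
- ni2_c
- so4_c
- zn2_c
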