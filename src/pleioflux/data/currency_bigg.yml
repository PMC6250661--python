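# The 14 currency metabolites, BiGG namespace (base ids; compartment
# suffixes are resolved at run time). Each entry defines the reversible,
# unbounded interconversion added to make the cofactor freely available,
#
#     charged <=> discharged + balancing species
#
# Balancing species listed under `pseudo` are bookkeeping pools (protons
# donated to an external sink, electron carriers, transferred phosphoryl,
# acetyl or amino groups); they are created as boundary species with a free
# exchange so the half-reaction balances without touching real pools.
- name: ATP
  charged: atp
  discharged: adp
  balancing: {phosphoryl_pool: 1}
  pseudo: [phosphoryl_pool]
- name: CTP
  charged: ctp
  discharged: cdp
  balancing: {phosphoryl_pool: 1}
  pseudo: [phosphoryl_pool]
- name: GTP
  charged: gtp
  discharged: gdp
  balancing: {phosphoryl_pool: 1}
  pseudo: [phosphoryl_pool]
- name: UTP
  charged: utp
  discharged: udp
  balancing: {phosphoryl_pool: 1}
  pseudo: [phosphoryl_pool]
- name: ITP
  charged: itp
  discharged: idp
  balancing: {phosphoryl_pool: 1}
  pseudo: [phosphoryl_pool]
- name: NADH
  charged: nadh
  discharged: nad
  balancing: {proton_pool: 1, electron_pool: 2}
  pseudo: [proton_pool, electron_pool]
- name: NADPH
  charged: nadph
  discharged: nadp
  balancing: {proton_pool: 1, electron_pool: 2}
  pseudo: [proton_pool, electron_pool]
- name: FADH2
  charged: fadh2
  discharged: fad
  balancing: {proton_pool: 2, electron_pool: 2}
  pseudo: [proton_pool, electron_pool]
- name: FMNH2
  charged: fmnh2
  discharged: fmn
  balancing: {proton_pool: 2, electron_pool: 2}
  pseudo: [proton_pool, electron_pool]
- name: Q8H2
  charged: q8h2
  discharged: q8
  balancing: {proton_pool: 2, electron_pool: 2}
  pseudo: [proton_pool, electron_pool]
- name: MQL8
  charged: mql8
  discharged: mqn8
  balancing: {proton_pool: 2, electron_pool: 2}
  pseudo: [proton_pool, electron_pool]
- name: DMMQL8
  charged: 2dmmql8
  discharged: 2dmmq8
  balancing: {proton_pool: 2, electron_pool: 2}
  pseudo: [proton_pool, electron_pool]
- name: ACCOA
  charged: accoa
  discharged: coa
  balancing: {acetyl_pool: 1}
  pseudo: [acetyl_pool]
- name: GLU
  charged: glu__L
  discharged: akg
  balancing: {amino_pool: 1}
  pseudo: [amino_pool]
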