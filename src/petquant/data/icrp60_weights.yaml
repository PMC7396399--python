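# ICRP Publication 60 tissue weighting factors, adapted to the organ list of
# the adult male MIRD phantom as used by OLINDA/EXM-era dosimetry software.
# Surrogates: thymus dose stands in for the oesophagus; testes for the
# gonads in the male model.  The colon is composed from the upper and lower
# large intestine walls by their approximate mass split.
scheme: ICRP-60
weights:
  gonads: 0.20
  red_marrow: 0.12
  colon: 0.12
  lung: 0.12
  stomach: 0.12
  bladder: 0.05
  breast: 0.05
  liver: 0.05
  esophagus: 0.05
  thyroid: 0.05
  skin: 0.01
  bone_surface: 0.01
remainder_weight: 0.05
remainder:
  - adrenals
  - brain
  - small_intestine
  - kidneys
  - muscle
  - pancreas
  - spleen
  - thymus
  - uterus
surrogates:
  gonads: testes
  esophagus: thymus
composites:
  colon:
    uli_wall: 0.57
    lli_wall: 0.43
splitting_rule: true
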