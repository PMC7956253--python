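# Default mouse physiology for the whole-body nanoparticle PBPK model.
#
# Fractional organ volumes, capillary (residual) blood fractions and blood
# flows follow standard rodent reference compilations (Brown et al. 1997,
# Toxicol Ind Health 13:407-484), rounded to the precision those tables carry.
# Values that are modelling assumptions rather than reference data are marked.
#
# Units: body weight kg; cardiac output mL/h; volumes derived at tissue
# density 1 g/mL so mg/g and mg/mL coincide.
body_weight_kg: 0.02
cardiac_output_ml_h: 740.0      # ~13.98 L/h per kg^0.75 at 0.02 kg
allometric_exponent: 0.75       # cardiac output scaling with body weight
blood_pool_volume_fraction: 0.049   # circulating blood outside organ capillaries
venous_fraction: 0.667          # share of the blood pool in the venous reservoir
tumour_volume_ml: 0.55          # mid-range of the implanted-tumour volumes used
portal_routing: false           # spleen effluent direct to venous pool by default
organs:
  # lung sits in series with the heart and carries total cardiac output,
  # so its flow_fraction is 1 and is excluded from the parallel-sum check
  lung:         {volume_fraction: 0.007,  blood_volume_fraction: 0.50, flow_fraction: 1.0}
  liver:        {volume_fraction: 0.055,  blood_volume_fraction: 0.31, flow_fraction: 0.161}
  spleen:       {volume_fraction: 0.005,  blood_volume_fraction: 0.17, flow_fraction: 0.011}
  kidney:       {volume_fraction: 0.017,  blood_volume_fraction: 0.24, flow_fraction: 0.091}
  heart:        {volume_fraction: 0.005,  blood_volume_fraction: 0.26, flow_fraction: 0.066}
  # tumour volume comes from tumour_volume_ml above; flow is an assumption
  tumour:       {blood_volume_fraction: 0.07, flow_fraction: 0.01}
  # complements of the named organs and the blood pool
  rest_of_body: {volume_fraction: 0.8345, blood_volume_fraction: 0.04, flow_fraction: 0.661}
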