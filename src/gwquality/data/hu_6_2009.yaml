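# Groundwater contamination limits, Hungarian joint decree 6/2009 (IV. 14.)
# KvVM-EüM-FVM, for the eight parameters of the municipal monitoring profile.
# ideal_value is the quality-rating zero point (Vi): 0 for concentrations,
# 7 (neutrality) for pH. standard_permissible is Vs; pH additionally carries
# the decree's lower bound 6.5. cd_upper (CNi) defaults to Vs when omitted.
pH:
  unit: ""
  ideal_value: 7.0
  standard_permissible: 8.5
  lower_permissible: 6.5
EC:
  unit: "uS/cm"
  ideal_value: 0.0
  standard_permissible: 2500.0
NH4:
  unit: "mg/L"
  ideal_value: 0.0
  standard_permissible: 0.5
NO2:
  unit: "mg/L"
  ideal_value: 0.0
  standard_permissible: 0.5
NO3:
  unit: "mg/L"
  ideal_value: 0.0
  standard_permissible: 50.0
PO4:
  unit: "mg/L"
  ideal_value: 0.0
  standard_permissible: 0.5
COD:
  unit: "mg/L"
  ideal_value: 0.0
  standard_permissible: 4.5
Na:
  unit: "mg/L"
  ideal_value: 0.0
  standard_permissible: 200.0
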