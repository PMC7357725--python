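# Canonical column schema for the on-farm fertilizer trial database.
# One row = one treatment-control pair of maize plots. CSV dialect: UTF-8,
# comma separator, "." decimal point, empty string = missing value.
columns:
  study_id:      {kind: categorical, required: true,  description: opaque study label}
  site_id:       {kind: categorical, required: false, description: opaque site label}
  region:        {kind: categorical, required: true,  levels: [kenya, ssa_other]}
  yield_t_mean:  {kind: numeric, unit: kg/ha, required: true,  description: mean maize yield, fertilized plot}
  yield_c_mean:  {kind: numeric, unit: kg/ha, required: true,  description: mean maize yield, control plot}
  yield_t_sd:    {kind: numeric, unit: kg/ha, required: false, description: sd of fertilized-plot yields}
  yield_c_sd:    {kind: numeric, unit: kg/ha, required: false, description: sd of control-plot yields}
  yield_t_se:    {kind: numeric, unit: kg/ha, required: false, description: standard error alternative to sd}
  yield_c_se:    {kind: numeric, unit: kg/ha, required: false, description: standard error alternative to sd}
  yield_t_cv:    {kind: numeric, unit: "%",   required: false, description: coefficient of variation alternative to sd}
  yield_c_cv:    {kind: numeric, unit: "%",   required: false, description: coefficient of variation alternative to sd}
  n_t:           {kind: numeric, unit: count, required: true,  description: replicate count, fertilized arm}
  n_c:           {kind: numeric, unit: count, required: true,  description: replicate count, control arm}
  n_rate:        {kind: numeric, unit: kg N/ha, required: true, description: N application rate (FN)}
  soil_ph:       {kind: numeric, unit: "-",      required: false}
  total_c:       {kind: numeric, unit: g/kg,     required: false, description: soil total carbon}
  total_n:       {kind: numeric, unit: g/kg,     required: false, description: soil total nitrogen}
  p_olsen:       {kind: numeric, unit: mg/kg,    required: false, description: extractable P, Olsen method}
  p_bray1:       {kind: numeric, unit: mg/kg,    required: false, description: extractable P, Bray-1 method}
  p_bray2:       {kind: numeric, unit: mg/kg,    required: false, description: extractable P, Bray-2 method}
  exch_k:        {kind: numeric, unit: cmol/kg,  required: false, description: exchangeable potassium}
  exch_ca:       {kind: numeric, unit: cmol/kg,  required: false, description: exchangeable calcium}
  exch_mg:       {kind: numeric, unit: cmol/kg,  required: false, description: exchangeable magnesium}
  clay:          {kind: numeric, unit: "%",      required: false}
  sand:          {kind: numeric, unit: "%",      required: false}
  silt:          {kind: numeric, unit: "%",      required: false}
  rainfall:      {kind: numeric, unit: mm/season, required: false, description: average rainfall per growing season}
  altitude:      {kind: numeric, unit: m,        required: false}
  soil_order:    {kind: categorical, required: false, description: WRB-or-legacy soil group label, kept verbatim}
  texture_class: {kind: categorical, required: false, description: USDA texture class}
  aez:           {kind: categorical, required: false, description: agro-ecological zone}
  nutrient_type: {kind: categorical, required: false, levels: [N_only, NPK]}
  manager:       {kind: categorical, required: false, levels: [farmer, researcher]}
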