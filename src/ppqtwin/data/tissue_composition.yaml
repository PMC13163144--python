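# Tissue composition used by the tissue-composition (Rodgers & Rowland type)
# partition-coefficient prediction for a moderate-to-strong lipophilic base.
# Fractions are of total tissue volume: extracellular water (f_ew),
# intracellular water (f_iw), neutral lipids (f_nl), neutral phospholipids
# (f_np); acidic phospholipid content (ap) in mg/g tissue.  "rest" is a
# lumped average of the remaining carcass.

intracellular_ph: 7.0
plasma_ph: 7.4
blood_cell_ph: 7.22

tissues:
  adipose: {f_ew: 0.135, f_iw: 0.017, f_nl: 0.790, f_np: 0.0020, ap: 0.40}
  bone:    {f_ew: 0.100, f_iw: 0.346, f_nl: 0.074, f_np: 0.0011, ap: 0.67}
  brain:   {f_ew: 0.162, f_iw: 0.620, f_nl: 0.051, f_np: 0.0565, ap: 0.40}
  gut:     {f_ew: 0.282, f_iw: 0.475, f_nl: 0.049, f_np: 0.0163, ap: 2.41}
  heart:   {f_ew: 0.320, f_iw: 0.456, f_nl: 0.014, f_np: 0.0111, ap: 2.25}
  kidney:  {f_ew: 0.273, f_iw: 0.483, f_nl: 0.012, f_np: 0.0240, ap: 5.03}
  liver:   {f_ew: 0.161, f_iw: 0.573, f_nl: 0.014, f_np: 0.0240, ap: 4.56}
  lung:    {f_ew: 0.336, f_iw: 0.446, f_nl: 0.022, f_np: 0.0128, ap: 3.91}
  muscle:  {f_ew: 0.118, f_iw: 0.630, f_nl: 0.010, f_np: 0.0072, ap: 1.53}
  skin:    {f_ew: 0.382, f_iw: 0.291, f_nl: 0.060, f_np: 0.0044, ap: 1.32}
  spleen:  {f_ew: 0.207, f_iw: 0.579, f_nl: 0.0077, f_np: 0.0113, ap: 3.18}
  rest:    {f_ew: 0.280, f_iw: 0.450, f_nl: 0.040, f_np: 0.0100, ap: 2.00}

blood_cells: {f_iw: 0.603, f_nl: 0.0017, f_np: 0.0029, ap: 0.50}
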