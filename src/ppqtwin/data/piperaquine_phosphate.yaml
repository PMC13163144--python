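# Piperaquine phosphate compound file.
#
# Every entry is configuration, not code: refill from a preferred source at
# will.  Physicochemical constants are from the open piperaquine literature
# (lipophilic diprotic base, very highly protein-bound, blood:plasma < 1);
# clearance and the partition scalar are calibrated defaults chosen so the
# simulated healthy-pregnant population mean CL/F falls in the ~125-150 L/h
# range and the terminal half-life exceeds 20 days (see docs/methods.md).

molecular_weight_base: 535.5      # g/mol, piperaquine free base
molecular_weight_salt: 927.5      # g/mol, anhydrous tetraphosphate
# Salt-to-base dose conversion.  Two conventions are supported:
#   0.5774 = anhydrous tetraphosphate mass ratio 535.5/927.5
#   0.5828 = ratio implied by the trials' printed mean doses (10.24/17.57)
# Default: the trial-implied factor, so generated base doses reproduce the
# printed base-dose summaries.
salt_to_base_factor: 0.5828

log_p: 6.2
pka_values: [8.6, 6.5]            # diprotic base
fraction_unbound_plasma: 0.005    # highly protein-bound
blood_to_plasma_ratio: 0.9

absorption_rate_constant: 0.35    # 1/h, first-order, fasted state
fraction_absorbed: 0.5
lag_time: 0.5                     # h

# Clearance: whole-body apparent oral clearance (plasma CL/F) with
# allometric body-weight scaling, or hepatic intrinsic CYP3A4 clearance
# under the well-stirred model.
clearance_mode: whole-body-CL/F   # or intrinsic-CYP3A4
clearance_value: 130.0            # L/h (CL/F) at the reference body weight
clearance_reference_body_weight: 75.0   # kg
clearance_allometric_exponent: 0.75

kp_method: lipophilic-base-prediction   # or user-supplied-table
kp_scalar: 3.0
# kp_table:   # used when kp_method == user-supplied-table
#   adipose: 1.0
#   ...
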