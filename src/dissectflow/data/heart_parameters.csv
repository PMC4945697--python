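parameter,dissected,undissected
period_s,1.3,1.3
end_diastolic_volume_mm3,130000,130000
unstressed_volume_mm3,0.0,0.0
preload_g_per_mm_s2,533.320,533.320
time_to_max_elastance_s,0.410,0.420
time_to_relaxation_s,0.205,0.210
max_elastance_g_per_mm4_s2,0.460,0.400
min_elastance_g_per_mm4_s2,4.102e-3,4.102e-3
aortic_valve_resistance_g_per_mm4_s,1.0e-5,1.0e-5
aortic_valve_inductance_g_per_mm4,1.0e-5,1.0e-5
ventricular_resistance_s_per_mm3,5.0e-7,5.0e-7
mitral_valve_resistance_g_per_mm4_s,3.9453e-7,3.9453e-7
mitral_valve_inductance_g_per_mm4,1.334e-5,1.334e-5
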