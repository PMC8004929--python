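# Variant of the 28 g mouse fixture using generic literature-style cellular
# volume fractions (rounded to 2 decimals) instead of the Kp-ratio-calibrated
# set shipped in mouse_28g.csv. Volumes and flows are identical.
# hematocrit: 0.45
# body_weight_g: 28.0
tissue,V_total_mL,f_vascular,f_endothelial,f_interstitial,f_cellular,Q_blood_mL_per_h
blood,2.000,1.0,0.0,0.0,0.0,676.4
lung,0.204,0.260,0.005,0.185,0.55,676.4
heart,0.152,0.070,0.005,0.145,0.78,66.0
kidney,0.525,0.105,0.005,0.140,0.75,125.0
brain,0.485,0.030,0.005,0.195,0.77,21.5
muscle,11.300,0.026,0.005,0.139,0.83,157.0
bone,2.820,0.041,0.005,0.184,0.77,27.6
skin,5.020,0.019,0.005,0.376,0.60,50.5
adipose,1.980,0.010,0.005,0.175,0.81,24.4
thymus,0.100,0.030,0.005,0.315,0.65,2.2
small_intestine,0.728,0.024,0.005,0.271,0.70,106.0
large_intestine,0.314,0.021,0.005,0.274,0.70,31.5
spleen,0.127,0.170,0.005,0.255,0.57,14.9
pancreas,0.097,0.057,0.005,0.218,0.72,11.3
liver,1.930,0.115,0.005,0.240,0.64,18.7
other,1.500,0.030,0.005,0.215,0.75,19.8
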