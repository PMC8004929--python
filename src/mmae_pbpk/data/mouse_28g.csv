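# Whole-body physiology fixture for a nominal 28 g tumor-bearing mouse.
# Volumes and regional whole-blood flows assembled from standard rodent PBPK
# physiology tables; cellular volume fractions calibrated so that the ratio of
# the apparent to cellular-space-adjusted partition coefficients matches the
# package's default MMAE Kp table (see docs/methods.md, "Physiology fixture").
# Q_blood for the lung row is the cardiac output and equals the sum of all
# other tissue flows (liver row = hepatic artery only); the blood row carries
# the total venous return for bookkeeping and is excluded from that check.
# hematocrit: 0.45
# body_weight_g: 28.0
tissue,V_total_mL,f_vascular,f_endothelial,f_interstitial,f_cellular,Q_blood_mL_per_h
blood,2.000,1.0,0.0,0.0,0.0,676.4
lung,0.204,0.260,0.005,0.1911,0.5439,676.4
heart,0.152,0.070,0.005,0.1399,0.7851,66.0
kidney,0.525,0.105,0.005,0.1447,0.7453,125.0
brain,0.485,0.030,0.005,0.1895,0.7755,21.5
muscle,11.300,0.026,0.005,0.1412,0.8278,157.0
bone,2.820,0.041,0.005,0.1868,0.7672,27.6
skin,5.020,0.019,0.005,0.3802,0.5958,50.5
adipose,1.980,0.010,0.005,0.1777,0.8073,24.4
thymus,0.100,0.030,0.005,0.3150,0.6500,2.2
small_intestine,0.728,0.024,0.005,0.2710,0.7000,106.0
large_intestine,0.314,0.021,0.005,0.2740,0.7000,31.5
spleen,0.127,0.170,0.005,0.2508,0.5742,14.9
pancreas,0.097,0.057,0.005,0.2179,0.7201,11.3
liver,1.930,0.115,0.005,0.2432,0.6368,18.7
other,1.500,0.030,0.005,0.2150,0.7500,19.8
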