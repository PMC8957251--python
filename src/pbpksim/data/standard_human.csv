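organ,weight_kg,perfusion_l_min_kg,lipid_fraction,ecf_fraction,k_alb
vein,4.29,1.0,0.015,0.595,NA
artery,1.21,0.0,0.015,0.595,NA
liver,1.8,0.25,0.02,0.23,0.5
portal,1.5,0.75,0.016,0.3,0.35
kidney,0.31,4.0,0.0136,0.165,0.35
brain,1.4,0.56,0.0176,0,0.1
heart,0.33,0.8,0.0136,0.264,0.5
muscle,26.0,0.0225,0.0136,0.15,0.5
skin,2.6,0.1,0.0136,0.6,0.25
lung,0.536,-1.0,0.0136,0.2,0.35
tendon,3.0,0.01,0.0136,1,0.25
other,5.522,0.02,0.0136,0.2,0.25
adipose,8.758,0.074,0.8,1,0.35
adipose 2,8.758,0.01408,0.8,1,0.35
bone,4.0,0.0,0,0,0
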