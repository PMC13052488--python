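# six-layer skin stack: volume fractions, thickness, refractive index,
# mean vessel diameter, pulsatility flag, reduced scattering scale at 577 nm
name,Cm,Cb,Cw,Cf,d_mm,n,vd_mm,pulsatile,mu_s0
epidermis,0.01,0.00,0.20,0.00,0.1,1.33,0.00,0,3.3
capillary_loops,0.00,0.04,0.65,0.17,0.15,1.37,0.01,1,2.5
upper_plexus,0.00,0.02,0.65,0.17,0.08,1.40,0.02,1,2.5
reticular_dermis,0.00,0.004,0.65,0.17,1.2,1.40,0.02,0,2.5
deep_plexus,0.00,0.04,0.65,0.17,0.5,1.40,0.04,1,2.5
subcutis,0.00,0.03,0.05,0.90,5.0,1.44,0.05,0,1.8
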