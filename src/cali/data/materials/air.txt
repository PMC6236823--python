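# synthetic mass attenuation table for air
# generated by scripts/make_material_tables.py from a parametric
# cross-section model (Klein-Nishina + fitted Z^p/E^q absorption);
# approximate, for simulation fixtures only
# density_g_cm3 = 0.001205
# energy_keV  mu_over_rho_cm2_g
10.0  4.866877e+00
15.0  1.583976e+00
20.0  7.772335e-01
25.0  4.866420e-01
30.0  3.561148e-01
35.0  2.881845e-01
40.0  2.488144e-01
45.0  2.240024e-01
50.0  2.072635e-01
55.0  1.953101e-01
60.0  1.863526e-01
65.0  1.793587e-01
70.0  1.737036e-01
75.0  1.689936e-01
80.0  1.649713e-01
85.0  1.614637e-01
90.0  1.583509e-01
95.0  1.555479e-01
100.0  1.529931e-01
105.0  1.506410e-01
110.0  1.484573e-01
115.0  1.464156e-01
120.0  1.444954e-01
125.0  1.426805e-01
130.0  1.409580e-01
135.0  1.393172e-01
140.0  1.377494e-01
145.0  1.362474e-01
150.0  1.348052e-01
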