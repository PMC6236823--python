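# synthetic mass attenuation table for delrin
# generated by scripts/make_material_tables.py from a parametric
# cross-section model (Klein-Nishina + fitted Z^p/E^q absorption);
# approximate, for simulation fixtures only
# density_g_cm3 = 1.41
# energy_keV  mu_over_rho_cm2_g
10.0  3.826728e+00
15.0  1.282457e+00
20.0  6.565091e-01
25.0  4.304661e-01
30.0  3.284655e-01
35.0  2.749969e-01
40.0  2.436894e-01
45.0  2.236937e-01
50.0  2.099836e-01
55.0  2.000103e-01
60.0  1.923857e-01
65.0  1.863085e-01
70.0  1.812932e-01
75.0  1.770332e-01
80.0  1.733280e-01
85.0  1.700423e-01
90.0  1.670822e-01
95.0  1.643806e-01
100.0  1.618891e-01
105.0  1.595713e-01
110.0  1.573999e-01
115.0  1.553536e-01
120.0  1.534159e-01
125.0  1.515734e-01
130.0  1.498155e-01
135.0  1.481333e-01
140.0  1.465196e-01
145.0  1.449683e-01
150.0  1.434740e-01
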