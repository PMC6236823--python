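# synthetic mass attenuation table for cortical_bone
# generated by scripts/make_material_tables.py from a parametric
# cross-section model (Klein-Nishina + fitted Z^p/E^q absorption);
# approximate, for simulation fixtures only
# density_g_cm3 = 1.92
# energy_keV  mu_over_rho_cm2_g
10.0  3.162503e+01
15.0  9.573175e+00
20.0  4.168076e+00
25.0  2.232306e+00
30.0  1.371883e+00
35.0  9.315686e-01
40.0  6.825743e-01
45.0  5.308066e-01
50.0  4.327041e-01
55.0  3.662010e-01
60.0  3.192996e-01
65.0  2.850914e-01
70.0  2.594050e-01
75.0  2.396195e-01
80.0  2.240309e-01
85.0  2.114983e-01
90.0  2.012375e-01
95.0  1.926976e-01
100.0  1.854832e-01
105.0  1.793057e-01
110.0  1.739505e-01
115.0  1.692562e-01
120.0  1.650990e-01
125.0  1.613836e-01
130.0  1.580351e-01
135.0  1.549943e-01
140.0  1.522139e-01
145.0  1.496558e-01
150.0  1.472888e-01
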