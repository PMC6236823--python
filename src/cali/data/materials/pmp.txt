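# synthetic mass attenuation table for pmp
# generated by scripts/make_material_tables.py from a parametric
# cross-section model (Klein-Nishina + fitted Z^p/E^q absorption);
# approximate, for simulation fixtures only
# density_g_cm3 = 0.83
# energy_keV  mu_over_rho_cm2_g
10.0  1.965309e+00
15.0  7.368572e-01
20.0  4.330928e-01
25.0  3.221671e-01
30.0  2.711145e-01
35.0  2.435351e-01
40.0  2.267135e-01
45.0  2.154157e-01
50.0  2.072149e-01
55.0  2.008786e-01
60.0  1.957338e-01
65.0  1.913910e-01
70.0  1.876129e-01
75.0  1.842487e-01
80.0  1.811992e-01
85.0  1.783963e-01
90.0  1.757926e-01
95.0  1.733535e-01
100.0  1.710535e-01
105.0  1.688732e-01
110.0  1.667976e-01
115.0  1.648147e-01
120.0  1.629150e-01
125.0  1.610906e-01
130.0  1.593350e-01
135.0  1.576426e-01
140.0  1.560086e-01
145.0  1.544290e-01
150.0  1.529001e-01
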