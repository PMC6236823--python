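# synthetic mass attenuation table for blood
# generated by scripts/make_material_tables.py from a parametric
# cross-section model (Klein-Nishina + fitted Z^p/E^q absorption);
# approximate, for simulation fixtures only
# density_g_cm3 = 1.058
# energy_keV  mu_over_rho_cm2_g
10.0  5.075833e+00
15.0  1.660363e+00
20.0  8.208805e-01
25.0  5.183658e-01
30.0  3.823772e-01
35.0  3.115176e-01
40.0  2.703775e-01
45.0  2.443901e-01
50.0  2.268083e-01
55.0  2.142116e-01
60.0  2.047378e-01
65.0  1.973128e-01
70.0  1.912861e-01
75.0  1.862478e-01
80.0  1.819300e-01
85.0  1.781523e-01
90.0  1.747897e-01
95.0  1.717537e-01
100.0  1.689800e-01
105.0  1.664208e-01
110.0  1.640405e-01
115.0  1.618112e-01
120.0  1.597117e-01
125.0  1.577248e-01
130.0  1.558370e-01
135.0  1.540369e-01
140.0  1.523156e-01
145.0  1.506653e-01
150.0  1.490795e-01
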