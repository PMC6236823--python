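# synthetic mass attenuation table for acrylic
# generated by scripts/make_material_tables.py from a parametric
# cross-section model (Klein-Nishina + fitted Z^p/E^q absorption);
# approximate, for simulation fixtures only
# density_g_cm3 = 1.19
# energy_keV  mu_over_rho_cm2_g
10.0  3.113129e+00
15.0  1.071207e+00
20.0  5.682993e-01
25.0  3.862502e-01
30.0  3.037456e-01
35.0  2.602051e-01
40.0  2.344708e-01
45.0  2.178370e-01
50.0  2.062699e-01
55.0  1.977233e-01
60.0  1.910822e-01
65.0  1.857025e-01
70.0  1.811936e-01
75.0  1.773084e-01
80.0  1.738852e-01
85.0  1.708144e-01
90.0  1.680198e-01
95.0  1.654469e-01
100.0  1.630561e-01
105.0  1.608174e-01
110.0  1.587083e-01
115.0  1.567112e-01
120.0  1.548122e-01
125.0  1.530001e-01
130.0  1.512658e-01
135.0  1.496019e-01
140.0  1.480019e-01
145.0  1.464606e-01
150.0  1.449734e-01
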