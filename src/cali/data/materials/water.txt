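# synthetic mass attenuation table for water
# generated by scripts/make_material_tables.py from a parametric
# cross-section model (Klein-Nishina + fitted Z^p/E^q absorption);
# approximate, for simulation fixtures only
# density_g_cm3 = 1.0
# energy_keV  mu_over_rho_cm2_g
10.0  4.891499e+00
15.0  1.606066e+00
20.0  7.984290e-01
25.0  5.072967e-01
30.0  3.763489e-01
35.0  3.080535e-01
40.0  2.683505e-01
45.0  2.432280e-01
50.0  2.261957e-01
55.0  2.139633e-01
60.0  2.047392e-01
65.0  1.974901e-01
70.0  1.915900e-01
75.0  1.866444e-01
80.0  1.823955e-01
85.0  1.786694e-01
90.0  1.753458e-01
95.0  1.723394e-01
100.0  1.695881e-01
105.0  1.670459e-01
110.0  1.646783e-01
115.0  1.624586e-01
120.0  1.603659e-01
125.0  1.583838e-01
130.0  1.564990e-01
135.0  1.547008e-01
140.0  1.529802e-01
145.0  1.513297e-01
150.0  1.497432e-01
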