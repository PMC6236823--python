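# synthetic mass attenuation table for polystyrene
# generated by scripts/make_material_tables.py from a parametric
# cross-section model (Klein-Nishina + fitted Z^p/E^q absorption);
# approximate, for simulation fixtures only
# density_g_cm3 = 1.05
# energy_keV  mu_over_rho_cm2_g
10.0  2.087000e+00
15.0  7.645620e-01
20.0  4.379318e-01
25.0  3.189545e-01
30.0  2.644355e-01
35.0  2.351757e-01
40.0  2.174827e-01
45.0  2.057210e-01
50.0  1.972781e-01
55.0  1.908277e-01
60.0  1.856459e-01
65.0  1.813141e-01
70.0  1.775775e-01
75.0  1.742746e-01
80.0  1.712989e-01
85.0  1.685781e-01
90.0  1.660614e-01
95.0  1.637122e-01
100.0  1.615035e-01
105.0  1.594150e-01
110.0  1.574309e-01
115.0  1.555388e-01
120.0  1.537287e-01
125.0  1.519926e-01
130.0  1.503236e-01
135.0  1.487162e-01
140.0  1.471656e-01
145.0  1.456675e-01
150.0  1.442184e-01
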