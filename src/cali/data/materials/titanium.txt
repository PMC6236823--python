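# synthetic mass attenuation table for titanium
# generated by scripts/make_material_tables.py from a parametric
# cross-section model (Klein-Nishina + fitted Z^p/E^q absorption);
# approximate, for simulation fixtures only
# density_g_cm3 = 4.506
# energy_keV  mu_over_rho_cm2_g
10.0  1.363435e+02
15.0  4.080839e+01
20.0  1.740060e+01
25.0  9.024368e+00
30.0  5.306964e+00
35.0  3.409366e+00
40.0  2.340295e+00
45.0  1.692087e+00
50.0  1.276021e+00
55.0  9.965131e-01
60.0  8.015994e-01
65.0  6.613660e-01
70.0  5.577580e-01
75.0  4.794357e-01
80.0  4.190316e-01
85.0  3.716164e-01
90.0  3.338067e-01
95.0  3.032275e-01
100.0  2.781777e-01
105.0  2.574171e-01
110.0  2.400270e-01
115.0  2.253166e-01
120.0  2.127597e-01
125.0  2.019507e-01
130.0  1.925733e-01
135.0  1.843784e-01
140.0  1.771680e-01
145.0  1.707832e-01
150.0  1.650956e-01
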