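# synthetic mass attenuation table for aluminum
# generated by scripts/make_material_tables.py from a parametric
# cross-section model (Klein-Nishina + fitted Z^p/E^q absorption);
# approximate, for simulation fixtures only
# density_g_cm3 = 2.699
# energy_keV  mu_over_rho_cm2_g
10.0  2.535418e+01
15.0  7.693151e+00
20.0  3.363940e+00
25.0  1.813211e+00
30.0  1.123710e+00
35.0  7.706765e-01
40.0  5.708817e-01
45.0  4.489681e-01
50.0  3.700480e-01
55.0  3.164489e-01
60.0  2.785613e-01
65.0  2.508515e-01
70.0  2.299784e-01
75.0  2.138422e-01
80.0  2.010776e-01
85.0  1.907702e-01
90.0  1.822917e-01
95.0  1.752002e-01
100.0  1.691787e-01
105.0  1.639955e-01
110.0  1.594786e-01
115.0  1.554980e-01
120.0  1.519545e-01
125.0  1.487713e-01
130.0  1.458881e-01
135.0  1.432573e-01
140.0  1.408407e-01
145.0  1.386075e-01
150.0  1.365325e-01
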