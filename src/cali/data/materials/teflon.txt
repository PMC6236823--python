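# synthetic mass attenuation table for teflon
# generated by scripts/make_material_tables.py from a parametric
# cross-section model (Klein-Nishina + fitted Z^p/E^q absorption);
# approximate, for simulation fixtures only
# density_g_cm3 = 2.16
# energy_keV  mu_over_rho_cm2_g
10.0  6.264167e+00
15.0  1.995877e+00
20.0  9.478148e-01
25.0  5.709641e-01
30.0  4.022322e-01
35.0  3.148644e-01
40.0  2.645981e-01
45.0  2.332261e-01
50.0  2.123169e-01
55.0  1.975971e-01
60.0  1.867412e-01
65.0  1.784088e-01
70.0  1.717890e-01
75.0  1.663713e-01
80.0  1.618226e-01
85.0  1.579191e-01
90.0  1.545062e-01
95.0  1.514748e-01
100.0  1.487457e-01
105.0  1.462608e-01
110.0  1.439764e-01
115.0  1.418592e-01
120.0  1.398833e-01
125.0  1.380286e-01
130.0  1.362788e-01
135.0  1.346209e-01
140.0  1.330442e-01
145.0  1.315401e-01
150.0  1.301010e-01
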