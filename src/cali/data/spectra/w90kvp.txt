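# synthetic 90 kVp tungsten spectrum (Kramers bremsstrahlung model,
# 8 mm Al total filtration); generated by
# scripts/make_material_tables.py; approximate
# energy_keV  relative_fluence
16.0  1.253822e-06
17.0  1.202887e-05
18.0  7.238062e-05
19.0  3.065787e-04
20.0  9.928417e-04
21.0  2.611025e-03
22.0  5.830812e-03
23.0  1.143443e-02
24.0  2.020102e-02
25.0  3.279201e-02
26.0  4.966755e-02
27.0  7.104645e-02
28.0  9.690669e-02
29.0  1.270150e-01
30.0  1.609727e-01
31.0  1.982660e-01
32.0  2.383134e-01
33.0  2.805068e-01
34.0  3.242423e-01
35.0  3.689435e-01
36.0  4.140762e-01
37.0  4.591573e-01
38.0  5.037585e-01
39.0  5.475068e-01
40.0  5.900822e-01
41.0  6.312141e-01
42.0  6.706771e-01
43.0  7.082859e-01
44.0  7.438909e-01
45.0  7.773728e-01
46.0  8.086393e-01
47.0  8.376202e-01
48.0  8.642646e-01
49.0  8.885372e-01
50.0  9.104161e-01
51.0  9.298901e-01
52.0  9.469570e-01
53.0  9.616214e-01
54.0  9.738939e-01
55.0  9.837893e-01
56.0  9.913259e-01
57.0  9.965245e-01
58.0  9.994079e-01
59.0  1.000000e+00
60.0  9.983256e-01
61.0  9.944098e-01
62.0  9.882780e-01
63.0  9.799553e-01
64.0  9.694664e-01
65.0  9.568355e-01
66.0  9.420864e-01
67.0  9.252419e-01
68.0  9.063242e-01
69.0  8.853545e-01
70.0  8.623534e-01
71.0  8.373405e-01
72.0  8.103344e-01
73.0  7.813530e-01
74.0  7.504135e-01
75.0  7.175318e-01
76.0  6.827235e-01
77.0  6.460030e-01
78.0  6.073843e-01
79.0  5.668803e-01
80.0  5.245035e-01
81.0  4.802655e-01
82.0  4.341773e-01
83.0  3.862495e-01
84.0  3.364917e-01
85.0  2.849134e-01
86.0  2.315231e-01
87.0  1.763291e-01
88.0  1.193392e-01
89.0  6.056053e-02
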