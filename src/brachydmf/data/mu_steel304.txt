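# material: steel304 -- stainless steel type 304, approximated by elemental iron coefficients at 8.0 g/cm^3 (Cr/Ni are adjacent-Z to Fe)
# density_g_cm3: 8.0
# electrons_per_gram_Z_over_A: 0.46557
# provenance: mass attenuation (with coherent) and mass energy-absorption coefficients transcribed from standard reference photon cross-section compilations (NIST-style grid);
#   the without-coherent column subtracts a power-law coherent model A/E^1.9 with A=0.00027 cm^2 MeV^1.9/g, capped at 8% of the total and at half the (mu - muen) gap.
# columns: energy_MeV  mu_over_rho_total_nocoherent_cm2_g  mu_over_rho_total_withcoherent_cm2_g  muen_over_rho_cm2_g
0.001000  9.068500e+03  9.085000e+03  9.052000e+03
0.001500  3.393500e+03  3.399000e+03  3.388000e+03
0.002000  1.623000e+03  1.626000e+03  1.620000e+03
0.003000  5.555000e+02  5.576000e+02  5.534000e+02
0.004000  2.546500e+02  2.567000e+02  2.526000e+02
0.005000  1.382500e+02  1.398000e+02  1.367000e+02
0.006000  8.353000e+01  8.484000e+01  8.222000e+01
0.007111  5.213500e+01  5.319000e+01  5.108000e+01
0.007113  4.038457e+02  4.071000e+02  3.300000e+02
0.008000  3.029969e+02  3.056000e+02  2.440000e+02
0.010000  1.688964e+02  1.706000e+02  1.369000e+02
0.015000  5.629152e+01  5.708000e+01  4.896000e+01
0.020000  2.522354e+01  2.568000e+01  2.260000e+01
0.030000  7.964732e+00  8.176000e+00  7.251000e+00
0.040000  3.506693e+00  3.629000e+00  3.155000e+00
0.050000  1.877957e+00  1.958000e+00  1.638000e+00
0.060000  1.148392e+00  1.205000e+00  9.555000e-01
0.080000  5.624288e-01  5.952000e-01  4.104000e-01
0.100000  3.502531e-01  3.717000e-01  2.177000e-01
0.150000  1.864736e-01  1.964000e-01  7.961000e-02
0.200000  1.402535e-01  1.460000e-01  4.825000e-02
0.300000  1.072403e-01  1.099000e-01  3.361000e-02
0.400000  9.246025e-02  9.400000e-02  3.039000e-02
0.500000  8.313232e-02  8.414000e-02  2.914000e-02
0.600000  7.632735e-02  7.704000e-02  2.836000e-02
0.800000  6.657743e-02  6.699000e-02  2.714000e-02
1.000000  5.968000e-02  5.995000e-02  2.603000e-02
1.250000  5.332330e-02  5.350000e-02  2.472000e-02
1.500000  4.870503e-02  4.883000e-02  2.360000e-02
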