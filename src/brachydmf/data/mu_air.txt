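# material: air -- dry air, near sea level
# density_g_cm3: 0.001205
# electrons_per_gram_Z_over_A: 0.49919
# provenance: mass attenuation (with coherent) and mass energy-absorption coefficients transcribed from standard reference photon cross-section compilations (NIST-style grid);
#   the without-coherent column subtracts a power-law coherent model A/E^1.9 with A=3.2e-05 cm^2 MeV^1.9/g, capped at 8% of the total and at half the (mu - muen) gap.
# columns: energy_MeV  mu_over_rho_total_nocoherent_cm2_g  mu_over_rho_total_withcoherent_cm2_g  muen_over_rho_cm2_g
0.001000  3.602500e+03  3.606000e+03  3.599000e+03
0.001500  1.189500e+03  1.191000e+03  1.188000e+03
0.002000  5.270500e+02  5.279000e+02  5.262000e+02
0.003000  1.619500e+02  1.625000e+02  1.614000e+02
0.004000  7.712000e+01  7.788000e+01  7.636000e+01
0.005000  3.979000e+01  4.027000e+01  3.931000e+01
0.006000  2.305500e+01  2.341000e+01  2.270000e+01
0.008000  9.683500e+00  9.921000e+00  9.446000e+00
0.010000  4.931000e+00  5.120000e+00  4.742000e+00
0.015000  1.520551e+00  1.614000e+00  1.334000e+00
0.020000  7.238005e-01  7.779000e-01  5.389000e-01
0.030000  3.287608e-01  3.538000e-01  1.537000e-01
0.040000  2.340044e-01  2.485000e-01  6.833000e-02
0.050000  1.985135e-01  2.080000e-01  4.098000e-02
0.060000  1.807909e-01  1.875000e-01  3.041000e-02
0.080000  1.623160e-01  1.662000e-01  2.407000e-02
0.100000  1.515581e-01  1.541000e-01  2.325000e-02
0.150000  1.344235e-01  1.356000e-01  2.496000e-02
0.200000  1.226189e-01  1.233000e-01  2.672000e-02
0.300000  1.063848e-01  1.067000e-01  2.872000e-02
0.400000  9.530751e-02  9.549000e-02  2.949000e-02
0.500000  8.700057e-02  8.712000e-02  2.966000e-02
0.600000  8.046554e-02  8.055000e-02  2.953000e-02
0.800000  7.069110e-02  7.074000e-02  2.882000e-02
1.000000  6.354800e-02  6.358000e-02  2.789000e-02
1.250000  5.684906e-02  5.687000e-02  2.666000e-02
1.500000  5.173519e-02  5.175000e-02  2.547000e-02
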