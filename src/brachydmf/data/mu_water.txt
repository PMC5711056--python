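# material: water -- liquid water (H2O)
# density_g_cm3: 1.0
# electrons_per_gram_Z_over_A: 0.55508
# provenance: mass attenuation (with coherent) and mass energy-absorption coefficients transcribed from standard reference photon cross-section compilations (NIST-style grid);
#   the without-coherent column subtracts a power-law coherent model A/E^1.9 with A=3.5e-05 cm^2 MeV^1.9/g, capped at 8% of the total and at half the (mu - muen) gap.
# columns: energy_MeV  mu_over_rho_total_nocoherent_cm2_g  mu_over_rho_total_withcoherent_cm2_g  muen_over_rho_cm2_g
0.001000  4.071500e+03  4.078000e+03  4.065000e+03
0.001500  1.374000e+03  1.376000e+03  1.372000e+03
0.002000  6.162500e+02  6.173000e+02  6.152000e+02
0.003000  1.923000e+02  1.929000e+02  1.917000e+02
0.004000  8.234500e+01  8.278000e+01  8.191000e+01
0.005000  4.223000e+01  4.258000e+01  4.188000e+01
0.006000  2.434500e+01  2.464000e+01  2.405000e+01
0.008000  1.014250e+01  1.037000e+01  9.915000e+00
0.010000  5.136500e+00  5.329000e+00  4.944000e+00
0.015000  1.570790e+00  1.673000e+00  1.374000e+00
0.020000  7.504287e-01  8.096000e-01  5.503000e-01
0.030000  3.482134e-01  3.756000e-01  1.557000e-01
0.040000  2.524454e-01  2.683000e-01  6.947000e-02
0.050000  2.165241e-01  2.269000e-01  4.223000e-02
0.060000  1.985619e-01  2.059000e-01  3.190000e-02
0.080000  1.794519e-01  1.837000e-01  2.597000e-02
0.100000  1.679199e-01  1.707000e-01  2.546000e-02
0.150000  1.492132e-01  1.505000e-01  2.764000e-02
0.200000  1.362551e-01  1.370000e-01  2.967000e-02
0.300000  1.182552e-01  1.186000e-01  3.192000e-02
0.400000  1.059004e-01  1.061000e-01  3.279000e-02
0.500000  9.673938e-02  9.687000e-02  3.299000e-02
0.600000  8.946762e-02  8.956000e-02  3.284000e-02
0.800000  7.859652e-02  7.865000e-02  3.206000e-02
1.000000  7.068500e-02  7.072000e-02  3.103000e-02
1.250000  6.320709e-02  6.323000e-02  2.965000e-02
1.500000  5.752380e-02  5.754000e-02  2.833000e-02
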