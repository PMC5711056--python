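# Ir-192 photon emission spectrum: principal gamma lines plus
# K x-rays of the Pt/Os daughters, as compiled in radioactive
# decay data tables. Lines below 60 keV (L x-rays) are omitted;
# they do not penetrate the >1 cm water paths relevant here.
# columns: energy_MeV  intensity_photons_per_decay
0.061486  0.01200
0.063000  0.02070
0.065122  0.02630
0.066831  0.04480
0.071413  0.01000
0.075749  0.01530
0.077831  0.00410
0.136343  0.00183
0.201311  0.00471
0.205794  0.03310
0.283267  0.00266
0.295957  0.28720
0.308455  0.29680
0.316506  0.82860
0.374485  0.00726
0.416469  0.00669
0.468069  0.47810
0.484575  0.03189
0.489060  0.00438
0.588581  0.04517
0.604411  0.08200
0.612462  0.05340
0.884537  0.00291
1.061480  0.00053
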