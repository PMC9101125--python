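GAFF-like starting parameters for fluoro/hydroxy furanoses (representative values)
MASS
c3      12.010
os      16.000
oh      16.000
ho       1.008
hc       1.008
h1       1.008
h2       1.008
f       19.000

BOND
c3-c3    303.10    1.5350
c3-os    301.50    1.4390
c3-oh    314.10    1.4260
c3-f     363.80    1.3440
oh-ho    369.60    0.9740
c3-hc    337.30    1.0920
c3-h1    335.90    1.0930
c3-h2    334.70    1.0940

ANGLE
c3-c3-c3    63.210   110.630
c3-c3-os    67.780   108.420
c3-os-c3    62.010   111.550
c3-c3-oh    67.720   109.430
c3-c3-f     66.220   109.410
c3-oh-ho    47.090   108.160
f -c3-f     71.260   107.160
f -c3-h1    50.220   108.670
f -c3-oh    68.500   108.500
oh-c3-h1    50.970   109.880
os-c3-h1    50.840   108.820
os-c3-h2    51.750   108.700
hc-c3-hc    39.400   107.580
h1-c3-h1    39.180   108.460
h2-c3-h2    39.020   109.000
hc-c3-c3    46.370   110.050
h1-c3-c3    46.360   110.070

DIHE
X -c3-c3-X    1     0.15560     0.000     3.0
X -c3-os-X    1     0.38330     0.000     3.0
X -c3-oh-X    1     0.16670     0.000     3.0
c3-c3-c3-oh   1     0.15600     0.000     3.0
c3-c3-c3-f    1     0.15000     0.000     3.0
c3-c3-oh-ho   1     0.16000     0.000    -3.0
c3-c3-oh-ho   1     0.25000     0.000     1.0
f -c3-c3-f    1     1.20000   180.000     1.0
f -c3-c3-oh   1     0.75000   180.000     1.0
f -c3-c3-os   1     0.85000   180.000     1.0
oh-c3-c3-oh   1     1.17500     0.000     2.0

NONBON
  c3    1.9080    0.1094
  os    1.6837    0.1700
  oh    1.7210    0.2104
  ho    0.0000    0.0000
  hc    1.4870    0.0157
  h1    1.3870    0.0157
  h2    1.2870    0.0157
  f     1.7500    0.0610
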