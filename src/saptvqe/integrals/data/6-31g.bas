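# 6-31G split-valence basis (Hehre/Ditchfield/Pople; Hariharan-Pople).
# Columns: exponent, coefficient (S and P columns for SP shells).
element H
S
  18.73113700   0.03349460
   2.82539370   0.23472695
   0.64012170   0.81375733
S
   0.16127780   1.00000000

element He
S
  38.42163400   0.02376600
   5.77803000   0.15467900
   1.24177400   0.46963000
S
   0.29796400   1.00000000

element C
S
 3047.52490000   0.00183470
  457.36951000   0.01403730
  103.94869000   0.06884260
   29.21015500   0.23218440
    9.28666300   0.46794130
    3.16392700   0.36231200
SP
    7.86827240  -0.11933240   0.06899910
    1.88128850  -0.16085420   0.31642400
    0.54424930   1.14345640   0.74430830
SP
    0.16871440   1.00000000   1.00000000

element O
S
 5484.67170000   0.00183110
  825.23495000   0.01395010
  188.04696000   0.06844510
   52.96450000   0.23271430
   16.89757000   0.47019300
    5.79963530   0.35852090
SP
   15.53961600  -0.11077750   0.07087430
    3.59993360  -0.14802630   0.33975280
    1.01376180   1.13076700   0.72715860
SP
    0.27000580   1.00000000   1.00000000
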