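# STO-3G minimal basis (Hehre, Stewart, Pople). Columns: exponent, coefficient
# (S and P coefficient columns for SP shells). One block per contracted shell.
element H
S
   3.42525091   0.15432897
   0.62391373   0.53532814
   0.16885540   0.44463454

element He
S
   6.36242139   0.15432897
   1.15892300   0.53532814
   0.31364979   0.44463454

element C
S
  71.61683700   0.15432897
  13.04509600   0.53532814
   3.53051220   0.44463454
SP
   2.94124940  -0.09996723   0.15591627
   0.68348310   0.39951283   0.60768372
   0.22228990   0.70011547   0.39195739

element O
S
 130.70932000   0.15432897
  23.80886100   0.53532814
   6.44360830   0.44463454
SP
   5.03315130  -0.09996723   0.15591627
   1.16959610   0.39951283   0.60768372
   0.38038900   0.70011547   0.39195739
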