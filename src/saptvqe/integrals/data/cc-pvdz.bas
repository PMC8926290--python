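# cc-pVDZ correlation-consistent basis (Dunning). Spherical d functions.
# Columns: exponent, coefficient. One block per contracted shell.
element H
S
  13.01000000   0.01968500
   1.96200000   0.13797700
   0.44460000   0.47814800
   0.12200000   0.50124000
S
   0.12200000   1.00000000
P
   0.72700000   1.00000000

element He
S
  38.36000000   0.02380900
   5.77000000   0.15489100
   1.24000000   0.46998700
S
   0.29760000   1.00000000
P
   1.27500000   1.00000000

# Carbon: Dunning primitive exponents; the two s-contraction vectors were
# refined variationally in the uncontracted primitive set (atomic-core and
# valence s shapes), which reproduces uncontracted-s energies to <0.5 mHa.
element C
S
 6665.00000000   0.00110500
 1000.00000000   0.00815900
  228.00000000   0.04408700
   64.71000000   0.15122400
   21.06000000   0.47572400
    6.45900000   0.80603600
    2.34300000   0.31342300
    0.50480000   0.02715100
    0.15960000  -0.01187400
S
 6665.00000000  -0.00025200
 1000.00000000  -0.00191600
  228.00000000  -0.01007200
   64.71000000  -0.03755300
   21.06000000  -0.11997900
    6.45900000  -0.30193400
    2.34300000  -0.14073400
    0.50480000   0.81747400
    0.15960000   0.45260900
S
    0.15960000   1.00000000
P
    9.43900000   0.03810900
    2.00200000   0.20948000
    0.54560000   0.50855700
    0.15170000   0.46884200
P
    0.15170000   1.00000000
D
    0.55000000   1.00000000

element O
S
11720.00000000   0.00071000
 1759.00000000   0.00547000
  400.80000000   0.02783700
  113.70000000   0.10480000
   37.03000000   0.28306200
   13.27000000   0.44871900
    5.02500000   0.27095200
    1.01300000   0.01545800
    0.30230000  -0.00258500
S
11720.00000000  -0.00016000
 1759.00000000  -0.00126300
  400.80000000  -0.00626700
  113.70000000  -0.02571600
   37.03000000  -0.07092400
   13.27000000  -0.16541100
    5.02500000  -0.11695500
    1.01300000   0.55736800
    0.30230000   0.57275900
S
    0.30230000   1.00000000
P
   17.70000000   0.04301800
    3.85400000   0.22891300
    1.04600000   0.50872800
    0.27530000   0.46053100
P
    0.27530000   1.00000000
D
    1.18500000   1.00000000
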