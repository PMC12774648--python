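# Synthetic 3Di substitution matrix (stand-in; not the Foldseek-trained matrix).
# Diagonal 6, off-diagonal -3, symmetric.
 A  C  D  E  F  G  H  I  K  L  M  N  P  Q  R  S  T  V  W  Y
A  6 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3
C -3  6 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3
D -3 -3  6 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3
E -3 -3 -3  6 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3
F -3 -3 -3 -3  6 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3
G -3 -3 -3 -3 -3  6 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3
H -3 -3 -3 -3 -3 -3  6 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3
I -3 -3 -3 -3 -3 -3 -3  6 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3
K -3 -3 -3 -3 -3 -3 -3 -3  6 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3
L -3 -3 -3 -3 -3 -3 -3 -3 -3  6 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3
M -3 -3 -3 -3 -3 -3 -3 -3 -3 -3  6 -3 -3 -3 -3 -3 -3 -3 -3 -3
N -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3  6 -3 -3 -3 -3 -3 -3 -3 -3
P -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3  6 -3 -3 -3 -3 -3 -3 -3
Q -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3  6 -3 -3 -3 -3 -3 -3
R -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3  6 -3 -3 -3 -3 -3
S -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3  6 -3 -3 -3 -3
T -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3  6 -3 -3 -3
V -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3  6 -3 -3
W -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3  6 -3
Y -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3 -3  6
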