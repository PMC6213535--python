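# Kyte-Doolittle hydropathy, shifted and scaled to (0, 1]
# value = (KD + 5.0) / 9.5, rounded to 3 decimals
# The shift keeps every residue strictly positive so the intrinsic (H)
# reference distribution never vanishes on the support of O.
ALA 0.716
ARG 0.053
ASN 0.158
ASP 0.158
CYS 0.789
GLN 0.158
GLU 0.158
GLY 0.484
HIS 0.189
ILE 1.000
LEU 0.926
LYS 0.116
MET 0.726
PHE 0.821
PRO 0.358
SER 0.389
THR 0.400
TRP 0.379
TYR 0.337
VAL 0.968
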