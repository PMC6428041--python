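# Background amino-acid frequencies (percent) from the UniProtKB/Swiss-Prot
# database statistics; used as the default unigram null model.
# Values are renormalized to sum to 1 when loaded; override with any
# two-column <residue><TAB><frequency> table.
A	8.25
C	1.37
D	5.45
E	6.75
F	3.86
G	7.07
H	2.27
I	5.96
K	5.84
L	9.66
M	2.42
N	4.06
P	4.70
Q	3.93
R	5.53
S	6.56
T	5.34
V	6.87
W	1.08
Y	2.92
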