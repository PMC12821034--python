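# Four-Gaussian Cromer-Mann coefficients for neutral atoms
# (International Tables for Crystallography Vol. C, Table 6.1.1.4).
# f(s) = sum_i a_i * exp(-b_i * s^2) + c  with s = sin(theta)/lambda = q_A/(4*pi) in 1/A
# columns: element a1 a2 a3 a4 b1 b2 b3 b4 c
H	0.489918	0.262003	0.196767	0.049879	20.6593	7.74039	49.5519	2.20159	0.001305
C	2.31000	1.02000	1.58860	0.865000	20.8439	10.2075	0.568700	51.6512	0.215600
N	12.2126	3.13220	2.01250	1.16630	0.005700	9.89330	28.9975	0.582600	-11.5290
O	3.04850	2.28680	1.54630	0.867000	13.2771	5.70110	0.323900	32.9089	0.250800
P	6.43450	4.17910	1.78000	1.49080	1.90670	27.1570	0.526000	68.1645	1.11490
S	6.90530	5.20340	1.43790	1.58630	1.46790	22.2151	0.253600	56.1720	0.866900
Na	4.76260	3.17360	1.26740	1.11280	3.28500	8.84220	0.313600	129.424	0.676000
Cl	11.4604	7.19640	6.25560	1.64550	0.010400	1.16620	18.5194	47.7784	-9.55740
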