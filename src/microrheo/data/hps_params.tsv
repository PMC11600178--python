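res	mass	charge	sigma	lambda_kr	lambda_urry
A	71.08	0	5.04	0.730	0.603
R	156.19	1	6.56	0.000	0.559
N	114.10	0	5.68	0.432	0.588
D	115.09	-1	5.58	0.378	0.294
C	103.14	0	5.48	0.595	0.647
Q	128.13	0	6.02	0.514	0.559
E	129.11	-1	5.92	0.459	0.000
G	57.05	0	4.50	0.649	0.574
H	137.14	0	6.08	0.514	0.765
I	113.16	0	6.18	0.973	0.706
L	113.16	0	6.18	0.973	0.721
K	128.17	1	6.36	0.514	0.382
M	131.19	0	6.18	0.838	0.676
F	147.18	0	6.36	1.000	0.824
P	97.12	0	5.56	1.000	0.759
S	87.08	0	5.18	0.595	0.588
T	101.10	0	5.62	0.676	0.588
W	186.21	0	6.78	0.946	1.000
Y	163.18	0	6.46	0.865	0.897
V	99.07	0	5.86	0.892	0.665
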