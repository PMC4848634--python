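code	formula	mono_mass
G	C2H3NO	57.02146
A	C3H5NO	71.03711
S	C3H5NO2	87.03203
P	C5H7NO	97.05276
V	C5H9NO	99.06841
T	C4H7NO2	101.04768
C	C3H5NOS	103.00918
L	C6H11NO	113.08406
I	C6H11NO	113.08406
N	C4H6N2O2	114.04293
D	C4H5NO3	115.02694
Q	C5H8N2O2	128.05858
K	C6H12N2O	128.09496
E	C5H7NO3	129.04259
M	C5H9NOS	131.04048
H	C6H7N3O	137.05891
F	C9H9NO	147.06841
R	C6H12N4O	156.10111
Y	C9H9NO2	163.06333
W	C11H10N2O	186.07931
Hty	C10H11NO2	177.07898
MeAla	C4H7NO	85.05276
Ile	C6H11NO	113.08406
Tyr	C9H9NO2	163.06333
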