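	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0.1600	0.2300	-0.2000	-0.1500	0.3800	0.0900	-0.1300	0.3900	-0.2700	0.3700	0.3100	0.0200	-0.0200	0.0600	-0.0300	0.0100	0.0400	0.3800	0.4000	0.3000
C	0.2300	1.1000	-0.3300	-0.2800	0.7500	0.1600	-0.0600	0.6600	-0.3000	0.6400	0.5800	-0.0100	0.0500	0.0300	0.0400	0.0800	0.1100	0.6500	0.7700	0.6700
D	-0.2000	-0.3300	-0.6600	-0.6100	-0.1800	-0.2700	0.7100	-0.3700	0.8700	-0.3900	-0.4500	0.1600	0.0200	0.2000	0.8100	0.0500	0.0800	-0.3800	-0.1600	-0.2600
E	-0.1500	-0.2800	-0.6100	-0.5600	-0.1300	-0.2200	0.7600	-0.3200	0.9200	-0.3400	-0.4000	0.2100	0.0700	0.2500	0.8600	0.1000	0.1300	-0.3300	-0.1100	-0.2100
F	0.3800	0.7500	-0.1800	-0.1300	1.4000	0.3100	0.2900	1.1100	-0.0500	1.0900	1.0300	0.1400	0.2000	0.1800	0.3900	0.2300	0.2600	1.1000	1.4200	1.3200
G	0.0900	0.1600	-0.2700	-0.2200	0.3100	0.0200	-0.2000	0.3200	-0.3400	0.3000	0.2400	-0.0500	-0.0900	-0.0100	-0.1000	-0.0600	-0.0300	0.3100	0.3300	0.2300
H	-0.1300	-0.0600	0.7100	0.7600	0.2900	-0.2000	-0.3200	0.0000	-0.5600	-0.0200	-0.0800	0.1300	-0.0100	0.1700	-0.2200	0.0200	0.0500	-0.0100	0.3100	0.2100
I	0.3900	0.6600	-0.3700	-0.3200	1.1100	0.3200	0.0000	1.0200	-0.3400	1.0000	0.9400	-0.0500	0.1100	-0.0100	0.1000	0.1400	0.1700	1.0100	1.1300	1.0300
K	-0.2700	-0.3000	0.8700	0.9200	-0.0500	-0.3400	-0.5600	-0.3400	-0.7000	-0.3600	-0.4200	0.1900	-0.0500	0.2300	-0.4600	-0.0200	0.0100	-0.3500	-0.0300	-0.1300
L	0.3700	0.6400	-0.3900	-0.3400	1.0900	0.3000	-0.0200	1.0000	-0.3600	0.9800	0.9200	-0.0700	0.0900	-0.0300	0.0800	0.1200	0.1500	0.9900	1.1100	1.0100
M	0.3100	0.5800	-0.4500	-0.4000	1.0300	0.2400	-0.0800	0.9400	-0.4200	0.9200	0.8600	-0.1300	0.0300	-0.0900	0.0200	0.0600	0.0900	0.9300	1.0500	0.9500
N	0.0200	-0.0100	0.1600	0.2100	0.1400	-0.0500	0.1300	-0.0500	0.1900	-0.0700	-0.1300	0.1800	0.0400	0.2200	0.2300	0.0700	0.1000	-0.0600	0.1600	0.0600
P	-0.0200	0.0500	0.0200	0.0700	0.2000	-0.0900	-0.0100	0.1100	-0.0500	0.0900	0.0300	0.0400	-0.1000	0.0800	0.0900	-0.0700	-0.0400	0.1000	0.2200	0.1200
Q	0.0600	0.0300	0.2000	0.2500	0.1800	-0.0100	0.1700	-0.0100	0.2300	-0.0300	-0.0900	0.2200	0.0800	0.2600	0.2700	0.1100	0.1400	-0.0200	0.2000	0.1000
R	-0.0300	0.0400	0.8100	0.8600	0.3900	-0.1000	-0.2200	0.1000	-0.4600	0.0800	0.0200	0.2300	0.0900	0.2700	-0.1200	0.1200	0.1500	0.0900	0.4100	0.3100
S	0.0100	0.0800	0.0500	0.1000	0.2300	-0.0600	0.0200	0.1400	-0.0200	0.1200	0.0600	0.0700	-0.0700	0.1100	0.1200	-0.0400	-0.0100	0.1300	0.2500	0.1500
T	0.0400	0.1100	0.0800	0.1300	0.2600	-0.0300	0.0500	0.1700	0.0100	0.1500	0.0900	0.1000	-0.0400	0.1400	0.1500	-0.0100	0.0200	0.1600	0.2800	0.1800
V	0.3800	0.6500	-0.3800	-0.3300	1.1000	0.3100	-0.0100	1.0100	-0.3500	0.9900	0.9300	-0.0600	0.1000	-0.0200	0.0900	0.1300	0.1600	1.0000	1.1200	1.0200
W	0.4000	0.7700	-0.1600	-0.1100	1.4200	0.3300	0.3100	1.1300	-0.0300	1.1100	1.0500	0.1600	0.2200	0.2000	0.4100	0.2500	0.2800	1.1200	1.4400	1.3400
Y	0.3000	0.6700	-0.2600	-0.2100	1.3200	0.2300	0.2100	1.0300	-0.1300	1.0100	0.9500	0.0600	0.1200	0.1000	0.3100	0.1500	0.1800	1.0200	1.3400	1.2400
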