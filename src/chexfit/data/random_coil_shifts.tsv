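residue_name	CA	CB	C	N	HA
ALA	52.5	19.1	177.8	123.8	4.32
ARG	56.0	30.9	176.3	120.5	4.34
ASN	53.1	38.9	175.2	118.7	4.74
ASP	54.2	41.1	176.3	120.4	4.64
CYS	58.2	28.0	174.6	118.8	4.55
GLN	55.7	29.4	176.0	119.8	4.34
GLU	56.6	29.9	176.6	120.2	4.35
GLY	45.1		174.9	108.8	3.96
HIS	55.0	29.0	174.1	118.2	4.73
ILE	61.1	38.8	176.4	119.9	4.17
LEU	55.1	42.4	177.6	121.8	4.34
LYS	56.2	33.1	176.6	120.4	4.32
MET	55.4	32.9	176.3	119.6	4.48
PHE	57.7	39.6	175.8	120.3	4.62
PRO	63.3	32.1	177.3		4.42
SER	58.3	63.8	174.6	115.7	4.47
THR	61.8	69.8	174.7	113.6	4.35
TRP	57.5	29.6	176.1	121.3	4.66
TYR	57.9	38.8	175.9	120.3	4.55
VAL	62.2	32.9	176.3	119.2	4.12
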