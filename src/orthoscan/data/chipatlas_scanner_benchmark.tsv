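motif	tool	sn	ppv	accg
ASCL1	mixed_t_scanner	0.51	0.15	0.28
ASCL1	fimo	0.94	0.04	0.20
ASCL1	pscan	0.46	0.16	0.27
CDX2	mixed_t_scanner	0.44	0.18	0.28
CDX2	fimo	0.69	0.07	0.22
CDX2	pscan	0.43	0.20	0.30
DUX4	mixed_t_scanner	0.55	0.08	0.21
DUX4	fimo	0.78	0.04	0.18
DUX4	pscan	0.53	0.09	0.22
E2F1	mixed_t_scanner	0.61	0.80	0.70
E2F1	fimo	0.31	0.49	0.39
E2F1	pscan	0.58	0.81	0.69
ELK4	mixed_t_scanner	0.69	0.22	0.39
ELK4	fimo	0.93	0.10	0.31
ELK4	pscan	0.71	0.35	0.50
FLI1	mixed_t_scanner	0.48	0.77	0.61
FLI1	fimo	0.56	0.44	0.49
FLI1	pscan	0.42	0.81	0.58
GATA3	mixed_t_scanner	0.48	0.68	0.57
GATA3	fimo	0.50	0.32	0.40
GATA3	pscan	0.52	0.67	0.59
GLI2	mixed_t_scanner	0.52	0.37	0.44
GLI2	fimo	0.70	0.17	0.35
GLI2	pscan	0.30	0.33	0.31
HNF4G	mixed_t_scanner	0.46	0.27	0.35
HNF4G	fimo	0.86	0.10	0.30
HNF4G	pscan	0.29	0.29	0.29
JUND	mixed_t_scanner	0.35	0.71	0.50
JUND	fimo	0.57	0.33	0.43
JUND	pscan	0.30	0.69	0.46
MAFF	mixed_t_scanner	0.44	0.18	0.28
MAFF	fimo	0.67	0.08	0.23
MAFF	pscan	0.49	0.20	0.31
MEF2A	mixed_t_scanner	0.57	0.28	0.40
MEF2A	fimo	0.87	0.10	0.29
MEF2A	pscan	0.54	0.29	0.39
MXI1	mixed_t_scanner	0.40	0.72	0.54
MXI1	fimo	0.59	0.38	0.47
MXI1	pscan	0.34	0.72	0.49
NFE2	mixed_t_scanner	0.50	0.62	0.56
NFE2	fimo	0.62	0.29	0.42
NFE2	pscan	0.27	0.56	0.39
NFIC	mixed_t_scanner	0.34	0.59	0.45
NFIC	fimo	0.73	0.26	0.44
NFIC	pscan	0.32	0.58	0.43
NR2C2	mixed_t_scanner	0.49	0.13	0.25
NR2C2	fimo	0.91	0.05	0.21
NR2C2	pscan	0.31	0.12	0.19
NRF1	mixed_t_scanner	0.71	0.72	0.71
NRF1	fimo	0.87	0.38	0.58
NRF1	pscan	0.49	0.78	0.62
OTX2	mixed_t_scanner	0.60	0.51	0.55
OTX2	fimo	0.47	0.26	0.35
OTX2	pscan	0.37	0.56	0.46
PAX5	mixed_t_scanner	0.59	0.63	0.61
PAX5	fimo	0.82	0.29	0.49
PAX5	pscan	0.50	0.63	0.56
RUNX3	mixed_t_scanner	0.37	0.60	0.47
RUNX3	fimo	0.56	0.28	0.40
RUNX3	pscan	0.26	0.65	0.41
SP1	mixed_t_scanner	0.75	0.81	0.78
SP1	fimo	0.98	0.27	0.52
SP1	pscan	0.50	0.83	0.65
SPI1	mixed_t_scanner	0.42	0.78	0.57
SPI1	fimo	0.78	0.31	0.49
SPI1	pscan	0.46	0.78	0.60
SRF	mixed_t_scanner	0.36	0.63	0.48
SRF	fimo	0.41	0.31	0.36
SRF	pscan	0.46	0.62	0.53
TBX21	mixed_t_scanner	0.44	0.59	0.51
TBX21	fimo	0.74	0.26	0.44
TBX21	pscan	0.18	0.56	0.32
TCF7L2	mixed_t_scanner	0.40	0.62	0.50
TCF7L2	fimo	0.71	0.25	0.42
TCF7L2	pscan	0.29	0.59	0.42
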