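mirna	alias	RF_vs_FD	Rplus_vs_Rminus	Rplus_vs_Rminus_RF	Rplus_vs_Rminus_FD	RF_vs_FD_Rminus	RF_vs_FD_Rplus	cluster
hsa-let-7a-3p		1	0	0	0	0	0	5
gga-let-7a-5p		0	1	0	1	0	0	3
gga-let-7f-5p		1	1	0	1	1	0	3
gga-let-7k-5p		0	1	0	1	1	0	3
gga-miR-19a-3p		1	0	0	0	0	0	3
gga-miR-20a-5p		0	1	0	0	0	0	3
aca-miR-21-3p		0	1	0	0	0	0	3
gga-miR-21-5p		1	0	0	0	1	0	3
hsa-miR-30c-2-3p		1	0	0	0	1	0	3
gga-miR-30c-5p		1	0	0	0	0	0	5
gga-miR-30d		1	0	0	0	0	0	4
gga-miR-31-5p		1	0	0	0	1	0	3
gga-miR-32-5p		1	0	0	0	1	0	3
gga-miR-100-5p		1	0	0	0	1	0	4
gga-miR-101-3p		1	0	0	0	1	0	3
gga-miR-107-3p		0	1	0	0	0	0	3
gga-miR-122-5p		0	1	0	1	1	0	3
gga-miR-126-3p		1	0	0	0	0	0	3
ccr-miR-133a-5p		0	1	0	0	0	0	3
mmu-miR-144-5p		0	1	0	0	0	0	3
gga-miR-184-3p		0	1	0	1	0	0	3
gga-miR-193b-3p		1	0	0	0	1	0	1
gga-miR-202-5p		0	1	0	1	0	0	5
gga-miR-203		1	1	0	1	1	0	3
gga-miR-204	gga-miR-211	1	0	0	0	1	0	1
gga-miR-215-5p		1	0	0	1	1	0	3
gga-miR-223		1	0	0	0	1	0	5
gga-miR-301b-3p		1	0	0	0	1	0	3
gga-miR-365-3p		1	0	0	0	1	0	1
gga-miR-499-5p		0	1	0	1	0	0	3
gga-miR-499-3p		0	1	0	0	0	0	3
gga-miR-1736-3p		0	1	1	1	0	0	5
gga-miR-2188-3p		0	1	0	0	0	0	1
gga-miR-2188-5p		1	0	0	0	1	0	3
gga-miR-2954		1	0	0	0	1	0	1
mmu-miR-143-3p		0	0	0	0	1	0	3
mmu-miR-145a-5p		1	0	0	0	0	0	1
dre-miR-210-5p		1	0	0	0	0	0	5
ENSGALT00000042483-3p		0	1	1	1	0	0	5
ENSGALT00000043002-3p		0	1	0	0	0	0	2
ENSGALT00000043002-5p		0	1	0	0	0	0	2
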