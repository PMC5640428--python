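gene_symbol	uniprot_id	spectral_ratio	maxp	es	is	p5	p50	ps940	starred
KCC2b	Q91V14-2	349.0	1	X	X	X	X	X	
KCC2a	Q91V14-1	203.8	1	X	X	X	X	X	
PACSIN1	Q61644	136.0	1	X	X	X	X	X	
SLC44A1	Q6X893	54.0	1				X		
ATP2B4	Q6Q477	44.0	1	X			X		
KIF21B	Q9QXL1	41.0	1			X			
VCP	Q01853	24.0	1	X			X		
GLS	D3Z7P3	23.5	1			X	X		
RAB11FIP5	Q8R361	22.0	1	X			X	X	
SRCIN1	Q9QWI6	17.0	1	X			X	X	
RNF8	Q8VC56	16.0	1				X		
JAGN1	Q5XKN4	12.0	1				X		
PPFIA3	P60469	11.0	1	X			X	X	
SLC2A1	P17809	11.0	0.96				X		
YWHAE	P62259	10.0	0.99	X	X	X	X	X	
ACTN4	P57780	9.0	1	X			X		
CRMP1	P97427	8.0	1	X		X	X	X	
PITPNM2	Q6ZPQ6	8.0	1				X	X	
ACO2	Q99KI0	7.0	1	X		X	X	X	
COX4I1	P19783	6.0	0.96				X		
SLC4A10	Q5DTL9	6.0	1	X	X		X		
USP24	B1AY13	6.0	1			X			
YWHAG	P61982	6.0	0.96	X	X		X	X	
C1QB	P14106	5.0	0.89				X	X	
CCT6A	P80317	5.0	0.99	X		X			
CPSF6	Q6NVF9	5.0	0.99				X		
DDX5	Q61656	5.0	0.99	X		X			
DYNC1LI1	Q8R1Q8	5.0	0.78	X		X	X		
SEC23A	Q01405	5.0	0.99	X	X	X			
SLC8A2	Q8K596	5.0	0.99	X			X		
TRIM3	Q9R1R2	5.0	0.78	X	X	X	X		
CANX	P35564	4.5	1	X	X	X	X		
ATP5H	Q9DCX2	4.0	0.81				X		
ATP6V1E1	P50518	4.0	0.78	X		X	X		
DDX17	Q501J6	4.0	0.96			X			
DNAJA3	Q99M87	4.0	0.78	X			X	X	
DPYSL3	Q62188	4.0	0.96			X			
EWSR1	Q61545	4.0	1			X	X	X	
MAG	P20917	4.0	0.96	X	X		X		
MDH2	P08249	4.0	0.96	X			X		
RTCB	Q99LF4	4.0	0.98			X	X		
SNRPA	Q62189	4.0	0.96			X			
STOML2	Q99JB2	4.0	0.96	X		X			
STRN3	Q9ERG2	4.0	0.96				X		
YWHAQ	P68254	4.0	0.78	X			X		
INA	P46660	3.6	1	X			X		
ATP6V1F	Q9D1K2	3.5	0.95			X	X		
DCTN2	Q99KJ8	3.5	1	X		X	X		
CD47	Q61735	3.2	0.9		X		X		
ACOX3	Q9EPL9	3.0	0.78				X		
AP2B1	Q9DBG3	3.0	1	X	X		X		
APBA1	B2RUJ5	3.0	0.78			X			
ATP2A2	O55143	3.0	0.81	X			X	X	
CMPK1	Q9DBP5	3.0	0.78	X		X			
CRTC1	Q68ED7	3.0	0.78				X		
CTNNA2	Q61301	3.0	0.78	X		X			
FLII	Q9JJ28	3.0	0.78				X	X	
FXYD7	P59648	3.0	0.78				X		
GPM6A	P35802	3.0	0.93	X			X	X	
GRID2	Q61625	3.0	0.78	X			X		
NARS	Q8BP47	3.0	0.78				X		
NDUFA2	Q9CQ75	3.0	1				X		
NUDT21	Q9CQF3	3.0	0.78				X		
PPP1CA	P62137	3.0	0.78	X	X	X			
PPP2CA	P63330	3.0	0.78	X		X			
PRRT2	E9PUL5	3.0	0.78		X		X	X	
SFPQ	Q8VIJ6	3.0	1	X		X	X		
SIRT2	Q8VDQ8	3.0	0.89				X	X	
SLC1A2	P43006	3.0	0.69	X			X	X	
TCP1	P11983	3.0	0.78	X		X			
TRIO	Q0KL02	3.0	0.78	X		X			
PTN	P63089	2.7	1			X			
RAB2A	P53994	2.7	0.84	X			X		
NDUFS5	Q99LY9	2.5	0.82				X		
CCT2	P80314	2.5	1	X		X			
DNM1	P39053	2.5	1	X			X		
SLC25A11	Q9CR62	2.5	0.93	X	X		X		
DDX1	Q91VR5	2.4	0.89	X		X	X		
NEDD4L	Q8CFI0	2.4	0.91	X	X	X	X		
SYNGR3	Q8R191	2.4	1	X			X	X	
DLD	O08749	2.3	0.44	X		X	X	X	X
SNAP25	P60879	2.3	0.65	X		X	X	X	
DDX3X	Q62167	2.3	0.79	X		X	X	X	
CAMK2G	Q923T9	2.3	1	X			X		
FASN	P19096	2.3	1	X	X	X			
PKM	P52480	2.2	0.85				X		
NDUFA9	Q9DC69	2.1	0.96	X			X		
BASP1	Q91XV3	2.1	0.72	X			X	X	
CKB	Q04447	2.0	0.64	X			X		
COX6C	Q9CPQ1	2.0	0.89				X		
CSNK2A1	Q60737	2.0	0.84	X		X	X		
DHX9	O70133	2.0	0.44			X	X		X
DPYSL2	O08553	2.0	0.97	X		X	X	X	
EDC4	Q3UJB9	2.0	1				X		
FUS	P56959	2.0	0.94	X		X	X	X	
KCNAB2	P62482	2.0	0.92	X			X		
NDUFA8	Q9DCJ5	2.0	0.96	X			X		
NDUFS8	Q8K3J1	2.0	1				X		
PDIA6	Q922R8	2.0	0.89	X		X			
SFXN3	Q91V61	2.0	0.44	X			X		X
SLC25A22	Q9D6M3	2.0	0.89	X			X		
STMN2	P55821	2.0	1			X			
TNR	Q8BYI9	2.0	1	X	X		X		
TUBB4B	P68372	1.9	0.55				X	X	
ATP5C1	Q91VR2	1.9	0.6	X			X		
PPIA	P17742	1.8	0.74			X	X		
CKMT1	P30275	1.8	0.86	X		X	X	X	
COX5A	P12787	1.8	0.54				X		
C1QC	Q02105	1.8	0.43				X	X	X
NDUFS1	Q91VD9	1.8	0.88	X	X		X		
WWP1	Q8BZZ3	1.8	0.88				X		
ATP5B	P56480	1.7	0.38	X		X	X	X	
CCT5	P80316	1.7	0.81	X		X	X		
DCLK1	Q9JLM8	1.7	0.96	X	X	X			
SLC25A3	Q8VEM8	1.7	1	X	X		X		
SPTBN1	Q62261	1.7	0.7			X	X		
TUBB3	Q9ERD7	1.6	0.73			X	X	X	
CAMK2D	Q6PHZ2	1.6	0.82	X		X	X		
ATP6V0A1	Q9Z1G4	1.5	0.92	X			X		
CFL1	P18760	1.5	0.44	X		X	X		X
ATP1A2	Q6PIE5	1.5	0.04	X		X	X	X	X
ADGRL2	Q8JZZ7	1.5	0.89			X			
BSN	O88737	1.5	0.72	X			X		
DBT	P53395	1.5	0.86	X		X	X		
GTF2I	Q9ESZ8	1.5	0.89				X		
HELB	Q6NVF4	1.5	0.89				X		
HK1	P17710	1.5	0.89	X			X		
HMCN2	A2AJ76	1.5	0.89				X		
LGI3	Q8K406	1.5	0.89				X		
PC	Q05920	1.5	0.89				X		
RAB3IP	Q68EF0	1.5	0.89				X		
UQCR11	Q9CPX8	1.5	0.89				X		
ATP1A1	Q8VDN2	1.5	0.67	X	X		X	X	
ATP5O	Q9DB20	1.5	0.71			X	X		
NDUFA4	Q62425	1.4	0.51	X			X	X	
ATP6V0D1	P51863	1.4	0.53	X			X		
ACAT1	Q8QZT1	1.4	0.43	X		X	X		X
ATP2B2	Q9R0K7	1.4	0.47	X			X		X
TUBB4A	Q9D6F9	1.4	0.64			X	X	X	
GNB1	P62874	1.4	0.58	X	X	X	X	X	
C1QA	P98086	1.4	0.36			X	X		
NDUFA10	Q99LC3	1.4	0.65	X			X		
RAP2B	P61226	1.3	0.42		X		X		X
SYT1	P46096	1.3	0.65	X			X	X	
SLC1A3	P56564	1.3	0.9		X	X	X		
CAPRIN1	Q60865	1.3	0.56			X	X		
YWHAZ	P63101	1.3	0.44	X	X	X	X	X	X
ATP1A3	Q6PIC6	1.3	0	X		X	X	X	X
STX1B	P61264	1.3	0.45	X	X		X	X	X
NEFM	P08553	1.2	0.78	X			X		
DLST	Q9D2G2	1.2	0.72	X		X			
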