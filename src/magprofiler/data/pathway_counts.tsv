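pg_id	thermo_post_pre	meso_post_pre	prop	but	cfp	fad	wl	tca	fdhf	isa	me
DTU232	-4.65			24*		10*	8	14	1
DTU204	-2.98			12*		18*	9	7	4
DTU223	-0.17	-0.99					8	6	3		1
DTU183		0.43	14*	20*	32*	14*	8	11	3
DTU077		4.04		14*		14*	10	8	4
DTU122		2.15		1			8	11	5
DTU192		0.73					8	5	3
DTU236		0.64	18*	24*	29*		10	11	2
DTU093		0.55		29*	39*		9	32	1		1
DTU027		0.24					8	9	2
DTU021		-0.08		22*		21*	10	13	3
DTU095		-0.44	23*	28*	62*		9	27	3		1
DTU063		-2.33			33*		8	22
DTU008		-2.69	15*	15*	28*		8	15
DTU251	1.35		27*	26*		21*		21	1	14	1
DTU245	0.92		20*			9		29			3
DTU254	-0.21		22*	14*		13*		20	1
DTU156	-1.62		27*					24	2		7
DTU260	-4.63		22*	17*		17*		20		17	2
DTU041	-5.09		28*	41*		23*		28	1	14	6
DTU133	0.38	0.22	27*	25*		14*		26*			9
DTU101	0.10	-1.24	20*					24
DTU249	-1.51	-1.26	30*	36*		28*		31*	1		3
DTU255	3.16	2.56	20	23*		13*		31*	4		5
DTU248	-0.66	0.58	17*	24*		10*		20	5	18	6
DTU037	-1.23	-2.53	30*	33*		17*		24	3	24	2
DTU258	-7.15	-8.22	21*			11*		15
DTU131	-1.10	-3.81	28*	27*		19*		22*			9
DTU250	-1.64	-5.06	31*	25*		27*		23			6
DTU190		2.28	24*	45*		25*		15	8		4
DTU052		1.30	19*	35*	34*	38*		12	9		2
DTU030		0.11	16*	21*	44*			40	1
DTU019		-1.38	30*	27*	38*			20	6
DTU130		-4.66	23*	26*		13*		31*			9
DTU018		-5.21	20*	36*		17*		18	9		7
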