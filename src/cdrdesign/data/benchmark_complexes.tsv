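pdb	vl	h1	h2	h3	l1	l2	l3	ag_length	antigen
1a14	kappa	H1-13-1	H2-10-1	H3-15	L1-11-2	L2-8-1	L3-9-cis7-1	388	Neuraminidase
1a2y	kappa	H1-13-1	H2-9-1	H3-10	L1-11-2	L2-8-1	L3-9-cis7-2	129	Lysozyme C
1fe8	kappa	H1-13-1	H2-9-1	H3-9	L1-11-1	L2-8-1	L3-9-cis7-1	196	von Willebrand factor
1ic7	kappa	H1-13-1	H2-9-1	H3-7	L1-11-1	L2-8-1	L3-9-cis7-1	129	Lysozyme C
1iqd	kappa	H1-13-1	H2-10-1	H3-10	L1-12-1	L2-8-1	L3-9-1	156	Coagulation factor VIII
1n8z	kappa	H1-13-1	H2-10-1	H3-13	L1-11-1	L2-8-1	L3-9-cis7-1	607	ErbB-2
1ncb	kappa	H1-13-1	H2-10-1	H3-13	L1-11-2	L2-8-1	L3-9-cis7-1	389	Neuraminidase
1osp	kappa	H1-13-7	H2-9-3	H3-14	L1-11-2	L2-8-2	L3-9-cis7-1	257	Ozd [A
1uj3	kappa	H1-13-1	H2-10-1	H3-10	L1-11-2	L2-8-1	L3-9-cis7-1	205	Tissue factor
1w72	lambda	H1-13-1	H2-10-2	H3-15	L1-11-3	L2-8-1	L3-11-1	274	HLA-A1,b2-MG,peptide
2adf	kappa	H1-13-1	H2-10-1	H3-11	L1-11-2	L2-8-1	L3-8-1	196	von Willebrand factor
2b2x	kappa	H1-13-1	H2-9-1	H3-12	L1-10-1	L2-8-1	L3-9-cis7-1	223	Integrin alpha-1
2cmr	kappa	H1-13-3	H2-10-1	H3-12	L1-11-1	L2-8-1	L3-9-cis7-1	226	gp41
2dd8	lambda	H1-13-10	H2-10-1	H3-11	L1-11-3	L2-8-1	L3-10-1	202	Spike glycoprotein
2ghw	kappa	H1-13-1	H2-10-2	H3-10	L1-11-1	L2-8-1	L3-9-cis7-1	203	Spike glycoprotein
2vxt	kappa	H1-13-1	H2-10-1	H3-6	L1-11-1	L2-8-1	L3-9-cis7-1	157	Interleukin-18
2xqy	kappa	H1-13-1	H2-10-1	H3-11	L1-15-1	L2-8-1	L3-9-cis7-1	572	Envelope glycoprotein-H
2xwt	lambda	H1-13-1	H2-10-1	H3-12	L1-13-1	L2-8-2	L3-11-1	239	Thyrotropin receptor
2ypv	kappa	H1-13-1	H2-10-1	H3-12	L1-11-2	L2-8-1	L3-9-cis7-1	253	Lipoprotein
3bn9	kappa	H1-13-1	H2-10-2	H3-21	L1-11-1	L2-8-1	L3-9-cis7-1	241	MT-SP1
3cx5	kappa	H1-14-1	H2-9-1	H3-15	L1-11-2	L2-8-1	L3-9-cis7-1	185	Rieske Iron-sulfur protein
3ffd	lambda	H1-13-1	H2-10-2	H3-11	L1-12-3	L2-12-2	L3-13-1	108	PTH-related
3h3b	kappa	H1-13-1	H2-10-1	H3-13	L1-17-1	L2-8-1	L3-9-cis7-1	194	ErbB-2
3hi6	kappa	H1-13-1	H2-10-2	H3-13	L1-11-1	L2-8-1	L3-8-1	180	Integrin alpha-L
3k2u	kappa	H1-13-1	H2-10-1	H3-11	L1-11-1	L2-8-1	L3-9-cis7-1	257	HGF activator
3l95	kappa	H1-13-1	H2-10-1	H3-12	L1-11-1	L2-8-1	L3-9-2	244	NOTCH1
3mxw	kappa	H1-13-1	H2-10-1	H3-12	L1-11-1	L2-8-1	L3-9-cis7-1	169	Sonic hedgehog protein
3nid	kappa	H1-13-1	H2-10-1	H3-12	L1-11-2	L2-8-1	L3-9-cis7-1	457	Integrin alpha-IIb
3o2d	kappa	H1-13-1	H2-10-1	H3-15	L1-17-1	L2-8-1	L3-8-1	188	CD4
3rkd	kappa	H1-15-1	H2-9-1	H3-16	L1-11-2	L2-8-1	L3-9-cis7-2	146	Capsid protein
3s35	kappa	H1-13-1	H2-10-1	H3-10	L1-15-1	L2-8-1	L3-9-cis7-1	122	VGFR2
3uzq	kappa	H1-13-1	H2-10-1	H3-9	L1-15-1	L2-8-1	L3-9-cis7-1	114	Genome polyprotein
3w9e	kappa	H1-13-1	H2-10-1	H3-15	L1-12-1	L2-8-1	L3-8-2	306	Envelope glycoprotein D
4cmh	kappa	H1-13-1	H2-10-1	H3-13	L1-11-1	L2-8-1	L3-9-cis7-1	256	CD38
4dtg	kappa	H1-13-1	H2-10-2	H3-14	L1-16-1	L2-8-1	L3-9-cis7-1	66	TFPI
4dvr	kappa	H1-13-1	H2-10-1	H3-12	L1-11-1	L2-8-1	L3-8-1	313	gp160
4etq	kappa	H1-13-1	H2-10-1	H3-12	L1-10-1	L2-8-1	L3-9-cis7-1	269	IMV membrane protein
4ffv	kappa	H1-13-1	H2-10-1	H3-10	L1-10-1	L2-8-4	L3-9-cis7-1	730	Dipeptidyl peptidase 4
4fqj	lambda	H1-13-1	H2-10-1	H3-18	L1-13-1	L2-8-1	L3-11-1	304	Hemagglutinin
4g6j	kappa	H1-13-1	H2-10-2	H3-11	L1-11-1	L2-8-1	L3-9-cis7-1	158	Interleukin-1 beta
4g6m	kappa	H1-15-1	H2-9-1	H3-12	L1-11-2	L2-8-1	L3-9-cis7-1	150	Interleukin-1 beta
4h8w	lambda	H1-13-1	H2-10-2	H3-12	L1-14-2	L2-8-1	L3-11-1	353	gp160
4ki5	kappa	H1-13-1	H2-10-1	H3-15	L1-11-2	L2-8-2	L3-9-cis7-1	183	Factor VIII
4lvn	kappa	H1-14-1	H2-9-1	H3-13	L1-12-1	L2-8-1	L3-9-cis7-1	344	Subtilisin-like SP
4ot1	lambda	H1-13-1	H2-10-1	H3-24	L1-13-1	L2-8-2	L3-10-1	129	Envelope glycoprotein B
4qci	lambda	H1-13-1	H2-10-2	H3-13	L1-11-3	L2-8-1	L3-9-2	110	PDGFR Beta
4xnq	lambda	H1-14-1	H2-9-1	H3-16	L1-11-3	L2-8-1	L3-9-1	212	Hemagglutinin (Fragment)
4ydk	kappa	H1-13-1	H2-10-2	H3-22	L1-11-1	L2-8-1	L3-9-2	353	gp160
5b8c	kappa	H1-13-1	H2-10-1	H3-13	L1-15-1	L2-8-1	L3-9-cis7-1	139	PD1
5bv7	lambda	H1-13-1	H2-10-2	H3-19	L1-11-3	L2-8-1	L3-10-1	422	PC-sterol acyltransferase
5d93	kappa	H1-13-1	H2-10-1	H3-9	L1-10-1	L2-8-1	L3-9-cis7-1	244	Sulfhydryl oxidase 1
5d96	kappa	H1-13-1	H2-9-1	H3-12	L1-11-1	L2-8-1	L3-9-cis7-1	244	Sulfhydryl oxidase 1
5en2	kappa	H1-13-1	H2-10-1	H3-17	L1-11-1	L2-8-1	L3-9-cis7-1	141	Pre-glycoprotein GP
5f9o	kappa	H1-13-1	H2-10-1	H3-15	L1-11-1	L2-8-1	L3-8-1	352	gp120 core
5ggs	kappa	H1-13-3	H2-10-1	H3-13	L1-15-1	L2-8-1	L3-9-cis7-1	123	PD1
5hi4	lambda	H1-13-1	H2-10-2	H3-11	L1-13-2	L2-8-1	L3-9-1	132	Interleukin-17A homodimer
5j13	lambda	H1-13-1	H2-10-2	H3-15	L1-11-3	L2-8-2	L3-11-1	147	Thymic stromal lymphopoietin
5l6y	lambda	H1-13-1	H2-10-1	H3-15	L1-11-3	L2-8-1	L3-11-1	112	Interleukin-13
5mes	lambda	H1-13-1	H2-10-2	H3-12	L1-13-1	L2-8-1	L3-11-1	162	Mcl-1 homolog
5nuz	kappa	H1-13-1	H2-10-1	H3-13	L1-15-1	L2-8-1	L3-9-cis7-1	156	Pre-glycoprotein GP
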