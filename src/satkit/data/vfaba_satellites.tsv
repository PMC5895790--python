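satellite	monomer_bp	monomer_bp_variant	monomer_approx	pct_genome	mbp_1c	pct_at	max_at	max_cg	max_pupy	chip_input_ratio	centromere	notes
VfSat1	191		0	2.723	365.1	75.9	1.07	1.88	1.22	1.1		[Vf_TA_11]; similar to TR-9 of P. sativum
FokI	59	57	0	2.322	311.4	59.3	1.44	2.00	1.11	1.0		previously described
VfSat2	26		1	1.292	173.2	71.4	2.60	5.00	2.00	0.4		degenerate (GTT)n expansion
VfSat3	702		0	0.329	44.1	68.1	1.24	1.13	1.21	0.3		[Vf_TA_39]
TIII15	58		0	0.222	29.8	53.4	1.39	2.86	1.90	1.9		previously described
VfSat4	38		0	0.199	26.7	73.7	1.80	2.33	1.92	0.6		similar to VicTR-B
VfSat5	687		0	0.187	25.1	77.6	1.16	1.19	1.07	0.3
pVf7	169		0	0.182	24.4	55	1.07	1.00	1.04	0.3		previously described
VfSat6	50		0	0.132	17.6	64	1.91	1.57	1.78	103.6	CEN1	similar to TR-5 of P. sativum
VfSat7	44		0	0.102	13.7	70.5	1.21	1.17	1.2	103.2	CEN1
VfSat8	2033		0	0.061	8.1	71.7	1.68	1.03	1.46	91.3	CEN4	irregular internal subrepeats
VfSat9	963		0	0.055	7.4	77.6	1.02	1.77	1.00	0.2
VfSat10	1762		0	0.042	5.7	74.7	1.08	1.27	1.00	41.2	CEN1
VfSat11	1619		0	0.040	5.3	75.7	1.08	1.23	1.01	0.3
VfSat12	1004		0	0.038	5.1	74.2	1.12	1.27	1.02	0.2
VfSat13	47		0	0.036	4.8	68.1	2.56	1.14	1.76	149.2	CEN5
VfSat14	888		0	0.035	4.7	75.6	1.06	1.33	1.02	0.3
VfSat15	942		0	0.035	4.7	76.5	1.11	1.03	1.08	0.3		similar to TR-20 of P. sativum
VfSat16	1712		0	0.038	5.1	65.1	1.20	1.00	1.27	109.9	CEN6	[Vf_TA_157]
VfSat17	781		0	0.031	4.2	75	1.11	1.10	1.06	0.4
VfSat18	1172		0	0.031	4.2	79.7	1.11	1.03	1.08	0.3
VfSat19	1345		0	0.024	3.3	80.2	1.01	1.35	1.07	0.2
VfSat20	924		0	0.022	3	74.5	1.23	1.29	1.24	0.7
VfSat21	1057		0	0.017	2.3	74.3	1.02	1.35	1.10	0.2
VfSat22	1834		0	0.016	2.2	71.8	1.25	1.22	1.11	0.3
VfSat23	1325		0	0.008	1.1	73.3	1.17	1.41	1.18	81.9	CEN2
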