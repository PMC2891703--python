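gene_id	inhibition_amp1_mean	inhibition_amp1_sd	inhibition_amp2_mean	inhibition_amp2_sd
Sima	92.3	6.4	89.3	5.4
Tango	59.0	1.1
CG9769	91.9	3.7
Tango7	87.4	2.8	61.7	25.7
Trip1	87.5	3.4	84.7	11.8
CG8636	85.1	10.2
Pixie	74.5	7.9	77.7	14.2
CG4849	83.3	2.1	42.0	11
Ef2b	73.9	16.1	67.7	12
dTOR	89.5	5.5
dRaptor	89.3	2.3	66.9	3.1
dRheb	82.1	11.9	54.6	31.2
dPDK1	56.2	8.3	51.5	24.5
Brahma	83.9	11.6	84.8	0.6
Bap155/Moira	77.9	5.3	77.5	2.3
Snr1	38.0	15.3	28.2	11.4
Bap60	34.2	2.3	16.1	33.3
Dalao	35.3	7.9
Reptin	80.3	0.4	74.6	8.7
Pontin	75.3	4.6	67.3	17.5
CG14641	85.2	7.5	64.3	16.8
Prp8	72.5	20.5	71.1	2.3
Clipper	63.0	10.6
Symplekin	58.8	1.0	46.2	16.9
Peanuts	31.2	41.3
Argonaute 1	88.4	8.1	69.7	9.7
CSN3	60.3	2.6	30.5	3.7
CSN6	41.6	7.0
Spt6	88.9	2.7	75.2	0.1
CG2446	84.9	5.3
TER94	78.7	0.2	75.3	1.8
Cryptocephal	70.7	2.8
MBD-R2	69.9	8.9	31.9	18.9
CG7065	64.8	19.6
NSL1	63.0	12	62.8	11.7
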