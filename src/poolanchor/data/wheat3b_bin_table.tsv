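# Wheat chromosome 3B deletion-bin mapping data: cumulative contig length
# per bin, loci anchored by pooled-BAC hybridisation, and their barley 3H /
# rice Os01 mapping and collinearity counts.  Bins ordered telomere (short
# arm) -> centromere -> telomere (long arm).
bin	contig_length_mb	n_loci	barley_3h	barley_other	collinear_3h	rice_os01	rice_other	collinear_os01
3BS8-0.78-1.00	44.2	37	10	9	7	15	14	10
3BS9-0.57-0.78	43.2	43	12	4	9	22	16	16
3BS1-0.33-0.57	94.3	86	14	11	8	40	33	20
C-3BS1-0.33	58.3	34	9	1	4	23	7	16
C-3BL2-0.22	45.7	36	15	3	8	27	6	18
3BL2-0.22-0.50	74.9	78	25	10	21	47	26	38
3BL10-0.50-0.63	40.1	40	13	5	8	18	17	8
3BL7-0.63-1.00	155.5	165	55	14	37	93	57	59
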