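# Trinucleotide physicochemical indices DERIVED from authentic constants:
# gc_fraction / purine_fraction of the triplet, summed mononucleotide EIIP
# (Nair & Sreenadhan values), and summed SantaLucia (1998) nearest-neighbor
# dG37 / dH / dS of the two component dinucleotide steps. Standardized to
# mean 0 / SD 1 over the 64 trinucleotides before use by the encoders.
trinucleotide	gc_fraction	purine_fraction	eiip_sum	nn_dg37	nn_dh	nn_ds
AAA	0.000000	1.000000	0.3780	-2.00	-15.8	-44.4
AAC	0.333333	0.666667	0.3860	-2.44	-16.3	-44.6
AAG	0.333333	1.000000	0.3326	-2.28	-15.7	-43.2
AAT	0.000000	0.666667	0.3855	-1.88	-15.1	-42.6
ACA	0.333333	0.666667	0.3860	-2.89	-16.9	-45.1
ACC	0.666667	0.333333	0.3940	-3.28	-16.4	-42.3
ACG	0.666667	0.666667	0.3406	-3.61	-19.0	-49.6
ACT	0.333333	0.333333	0.3935	-2.72	-16.2	-43.4
AGA	0.333333	1.000000	0.3326	-2.58	-16.0	-43.2
AGC	0.666667	0.666667	0.3406	-3.52	-17.6	-45.4
AGG	0.666667	1.000000	0.2872	-3.12	-15.8	-40.9
AGT	0.333333	0.666667	0.3401	-2.72	-16.2	-43.4
ATA	0.000000	0.666667	0.3855	-1.46	-14.4	-41.7
ATC	0.333333	0.333333	0.3935	-2.18	-15.4	-42.6
ATG	0.333333	0.666667	0.3401	-2.33	-15.7	-43.1
ATT	0.000000	0.333333	0.3930	-1.88	-15.1	-42.6
CAA	0.333333	0.666667	0.3860	-2.45	-16.4	-44.9
CAC	0.666667	0.333333	0.3940	-2.89	-16.9	-45.1
CAG	0.666667	0.666667	0.3406	-2.73	-16.3	-43.7
CAT	0.333333	0.333333	0.3935	-2.33	-15.7	-43.1
CCA	0.666667	0.333333	0.3940	-3.29	-16.5	-42.6
CCC	1.000000	0.000000	0.4020	-3.68	-16.0	-39.8
CCG	1.000000	0.333333	0.3486	-4.01	-18.6	-47.1
CCT	0.666667	0.000000	0.4015	-3.12	-15.8	-40.9
CGA	0.666667	0.666667	0.3406	-3.47	-18.8	-49.4
CGC	1.000000	0.333333	0.3486	-4.41	-20.4	-51.6
CGG	1.000000	0.666667	0.2952	-4.01	-18.6	-47.1
CGT	0.666667	0.333333	0.3481	-3.61	-19.0	-49.6
CTA	0.333333	0.333333	0.3935	-1.86	-15.0	-42.3
CTC	0.666667	0.000000	0.4015	-2.58	-16.0	-43.2
CTG	0.666667	0.333333	0.3481	-2.73	-16.3	-43.7
CTT	0.333333	0.000000	0.4010	-2.28	-15.7	-43.2
GAA	0.333333	1.000000	0.3326	-2.30	-16.1	-44.4
GAC	0.666667	0.666667	0.3406	-2.74	-16.6	-44.6
GAG	0.666667	1.000000	0.2872	-2.58	-16.0	-43.2
GAT	0.333333	0.666667	0.3401	-2.18	-15.4	-42.6
GCA	0.666667	0.666667	0.3406	-3.69	-18.3	-47.1
GCC	1.000000	0.333333	0.3486	-4.08	-17.8	-44.3
GCG	1.000000	0.666667	0.2952	-4.41	-20.4	-51.6
GCT	0.666667	0.333333	0.3481	-3.52	-17.6	-45.4
GGA	0.666667	1.000000	0.2872	-3.14	-16.2	-42.1
GGC	1.000000	0.666667	0.2952	-4.08	-17.8	-44.3
GGG	1.000000	1.000000	0.2418	-3.68	-16.0	-39.8
GGT	0.666667	0.666667	0.2947	-3.28	-16.4	-42.3
GTA	0.333333	0.666667	0.3401	-2.02	-15.6	-43.7
GTC	0.666667	0.333333	0.3481	-2.74	-16.6	-44.6
GTG	0.666667	0.666667	0.2947	-2.89	-16.9	-45.1
GTT	0.333333	0.333333	0.3476	-2.44	-16.3	-44.6
TAA	0.000000	0.666667	0.3855	-1.58	-15.1	-43.5
TAC	0.333333	0.333333	0.3935	-2.02	-15.6	-43.7
TAG	0.333333	0.666667	0.3401	-1.86	-15.0	-42.3
TAT	0.000000	0.333333	0.3930	-1.46	-14.4	-41.7
TCA	0.333333	0.333333	0.3935	-2.75	-16.7	-44.9
TCC	0.666667	0.000000	0.4015	-3.14	-16.2	-42.1
TCG	0.666667	0.333333	0.3481	-3.47	-18.8	-49.4
TCT	0.333333	0.000000	0.4010	-2.58	-16.0	-43.2
TGA	0.333333	0.666667	0.3401	-2.75	-16.7	-44.9
TGC	0.666667	0.333333	0.3481	-3.69	-18.3	-47.1
TGG	0.666667	0.666667	0.2947	-3.29	-16.5	-42.6
TGT	0.333333	0.333333	0.3476	-2.89	-16.9	-45.1
TTA	0.000000	0.333333	0.3930	-1.58	-15.1	-43.5
TTC	0.333333	0.000000	0.4010	-2.30	-16.1	-44.4
TTG	0.333333	0.333333	0.3476	-2.45	-16.4	-44.9
TTT	0.000000	0.000000	0.4005	-2.00	-15.8	-44.4
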