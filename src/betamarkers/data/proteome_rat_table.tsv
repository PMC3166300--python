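accession	symbol	alpha	beta	brain	liver	protein_name	mrna_avfc	mrna_rank	protein_rank
O35165	Gosr2	-	0.00527	-	-	Golgi SNAP receptor complex member 2	1.8	1	1
Q7M0E3	Dstn	-	0.00329	-	-	Destrin	2.8	1	1
O35142	Copb2	-	0.00223	-	-	Coatomer subunit beta	1.9	1	1
P19103	Ppp1r1a	-	0.00219	-	-	Protein phosphatase 1 regulatory (inhibitor) subunit 1A	10.0	1	1
P28840	Pcsk1	-	0.00195	-	-	Proprotein convertase subtilisin/kexin type 1	22.3	1	1
P0C5H9	Armet	-	0.00168	-	-	Protein ARMET	3.5	1	1
Q6AYG5	Echdc1	-	0.00166	-	-	Enoyl CoA hydratase domain containing protein 1	1.7	2	1
P35571	Gpd2	-	0.00149	-	-	Glycerol 3 phosphate dehydrogenase mitochondrial	1.4	3	1
Q920J4	Txnl1	-	0.00120	-	-	Thioredoxin like protein 1	1.5	2	1
P12336	Slc2a2	-	0.00091	-	-	Solute carrier family 2 facilitated glucose transporter member 2	28.6	1	1
Q9R064	Gorasp2	-	0.00079	-	-	Golgi reassembly stacking protein 2	1.5	1	1
Q9ESI7	Dcx	-	0.00067	-	-	Neuronal migration protein doublecortin	12.0	1	1
Q9WVK7	Hadh	0.00162	0.01151	-	-	Hydroxyacyl coenzyme A dehydrogenase mitochondrial	6.0	1	1
P12969	Iapp	0.00252	0.00809	-	-	Islet amyloid polypeptide	105.6	1	1
P15087	Cpe	0.00809	0.00641	-	-	Carboxypeptidase E	12.3	1	2
P10362	Scg2	0.01099	0.00295	-	-	Secretogranin 2	67.3	2	2
P10354	Chga	0.00401	0.00254	-	-	Chromogranin A	14.3	2	2
P27682	Scg5	0.01081	0.00242	-	-	Neuroendocrine protein 7B2	19.4	2	2
Q4AEF8	Copg	0.00099	0.00228	-	-	Coatomer subunit gamma	2.1	1	1
P28841	Pcsk2	0.00901	0.00222	-	-	Neuroendocrine convertase 2	15.5	2	2
P47868	Scg3	0.00583	0.00104	-	-	Secretogranin 3	31.6	2	2
P61765	Stxbp1	-	0.00136	0.00420	-	Syntaxin binding protein 1	4.2	2	1
O35303	Dnm1l	-	0.00075	0.00089	-	Dynamin 1 like protein	1.4	3	2
O88600	Hspa4	0.00111	0.00169	0.00072	-	Heat shock 70 kDa protein 4	1.6	1	1
P61751	Arf4	0.00125	0.00106	0.00104	-	ADP ribosylation factor 4	2.0	1	2
Q62902	Lman1	-	0.00354	-	0.00227	Protein ERGIC 53	3.9	1	1
Q66HD0	Hsp90b1	0.00547	0.01348	-	0.00500	Endoplasmin	2.7	1	1
Q63081	Pdia6	0.00410	0.01173	-	0.00382	Protein disulfide isomerase A6	2.8	1	1
Q63617	Hyou1	0.00251	0.00836	-	0.00098	Hypoxia up regulated protein 1	4.5	1	1
Q9JI85	Nucb2	0.00155	0.00272	-	0.00057	Nucleobindin 2	6.8	1	1
Q66X93	Snd1	0.00090	0.00146	-	0.00148	Staphylococcal nuclease domain containing protein 1	2.1	1	2
P06761	Hspa5	0.00656	0.02272	0.00109	0.00913	78 kDa glucose regulated protein	2.9	1	1
P11598	Pdia3	0.00643	0.01311	0.00059	0.00631	Protein disulfide isomerase A3	2.7	1	1
Q6NYB7	Rab1A	0.00345	0.00347	0.00123	0.00129	Ras related protein Rab 1A	1.6	1	1
P18596	Atp2a3	0.00085	0.00307	0.00031	0.00051	Sarcoplasmic endoplasmic reticulum calcium ATPase 3	10.1	1	1
P05712	Rab2a	0.00221	0.00236	0.00127	0.00026	Ras related protein Rab 2A	1.4	1	1
P11507	Atp2a2	0.00109	0.00201	0.00131	0.00083	Sarcoplasmic endoplasmic reticulum calcium ATPase 2	2.4	2	1
Q63941	Rab3b	0.00186	0.00092	0.00050	<LLQ	Ras related protein Rab 3B	1.9	2	2
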