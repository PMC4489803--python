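# Replicate-pair call counts from a 17-sample kinome capture sequencing study
# (breast cancer fine-needle aspirates, duplicate or triplicate library prep +
# sequencing of the same genomic DNA). One row per replicate pair.
# allcall_* : unambiguous consensus nucleotide calls over the sequenced region
# snv_*     : SNV calls compared by genotype
# *_total   : printed mean of the two replicates' totals, mean(N1, N2)
sample_id	replicate_type	pair	allcall_concordant	allcall_total	snv_concordant	snv_total
294	dup	1	3402302	3402578	567	880
339	dup	1	3531773	3532119	634	930
494	dup	1	3527458	3527813	719	1056
506	dup	1	3260377	3260687	430	816
512	dup	1	3244079	3244357	412	692
524	dup	1	3596181	3596485	851	1186
647	dup	1	3554321	3554617	615	919
763	dup	1	3218631	3218829	394	643
792	dup	1	3301138	3301440	461	820
LP16	dup	1	3584535	3584858	846	1162
LP52	dup	1	3667521	3668018	803	1251
LP40	dup	1	3625547	3625983	989	1386
LP9	dup	1	3220037	3220209	414	672
M15	dup	1	3488692	3489012	558	846
571	trp	1	3448705	3449176	465	905
571	trp	2	3548364	3548819	813	1186
571	trp	3	3418099	3418572	487	916
658	trp	1	3417223	3417415	748	1024
658	trp	2	3497328	3497561	760	1083
658	trp	3	3548737	3548960	816	1108
LP63	trp	1	3537753	3538017	660	946
LP63	trp	2	3467992	3468237	636	912
LP63	trp	3	3510910	3511142	692	969
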