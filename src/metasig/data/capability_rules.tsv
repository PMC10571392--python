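capability	markers	version	note
acetate_synthesis	K00192,K00193,K00194,K00197,acetyl-CoA decarbonylase/synthase	1	Wood-Ljungdahl ACDS complex marker
propionate_synthesis_I	K23756,lactoyl-CoA dehydratase,lcdA	1	acrylate pathway
propionate_synthesis_II	K13922,propionaldehyde dehydrogenase,pduP	1	propanediol pathway
butyrate_synthesis_I	K01034,butyryl-CoA:acetate CoA-transferase,but	1	CoA-transferase route
butyrate_synthesis_II	K00929,butyrate kinase,buk	1	kinase route
bile_salt_hydrolase	K01442,bile salt hydrolase,cbh	1	primary bile-salt deconjugation
dehydroxylation_7ab	K15871,K15872,baiCD,baiE,7a/b-dehydroxylation	1	bai operon, secondary bile acids
hydroxysteroid_dehydrogenase	K00076,hydroxysteroid dehydrogenase,hdhA	1	7a-HSDH
is_precursor	K01667,tryptophanase,tnaA	1	indole -> indoxyl sulfate precursor
pcs_precursor	K01668,K18427,tyrosine phenol-lyase,4-hydroxyphenylacetate decarboxylase,tpl,hpdB	1	p-cresol -> p-cresyl sulfate precursor
pag_precursor	K00146,phenylacetaldehyde dehydrogenase,feaB,phenyllactate dehydratase,fldB,fldC	1	phenylacetate -> phenylacetylglutamine precursor
tmao_precursor	K20038,choline trimethylamine-lyase,cutC	1	TMA -> TMAO precursor
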