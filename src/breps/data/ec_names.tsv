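# Curated subset of the IUBMB enzyme nomenclature: full EC numbers map to
# recommended names, 1-3 level keys to class/subclass/sub-subclass descriptions.
1	Oxidoreductases
1.1	Acting on the CH-OH group of donors
1.1.1	With NAD(+) or NADP(+) as acceptor
1.1.2	With a cytochrome as acceptor
1.1.1.1	alcohol dehydrogenase
1.1.1.2	alcohol dehydrogenase (NADP(+))
1.1.1.27	L-lactate dehydrogenase
1.1.2.3	L-lactate dehydrogenase (cytochrome)
1.2	Acting on the aldehyde or oxo group of donors
1.2.1	With NAD(+) or NADP(+) as acceptor
1.2.1.3	aldehyde dehydrogenase (NAD(+))
1.11.1.6	catalase
1.14.13.39	nitric-oxide synthase (NADPH)
2	Transferases
2.1	Transferring one-carbon groups
2.1.3	Carboxy- and carbamoyltransferases
2.1.3.1	methylmalonyl-CoA carboxytransferase
2.1.1.37	DNA (cytosine-5-)-methyltransferase
2.7	Transferring phosphorus-containing groups
2.7.1	Phosphotransferases with an alcohol group as acceptor
2.7.1.1	hexokinase
2.7.1.2	glucokinase
2.7.2.3	phosphoglycerate kinase
3	Hydrolases
3.1	Acting on ester bonds
3.1.1	Carboxylic-ester hydrolases
3.1.1.3	triacylglycerol lipase
3.2.1.1	alpha-amylase
3.4.21.4	trypsin
3.5.1.5	urease
4	Lyases
4.1	Carbon-carbon lyases
4.1.1	Carboxy-lyases
4.1.1.39	ribulose-bisphosphate carboxylase
4.2.1.1	carbonic anhydrase
5	Isomerases
5.3	Intramolecular oxidoreductases
5.3.1	Interconverting aldoses and ketoses, and related compounds
5.3.1.9	glucose-6-phosphate isomerase
5.4.2.2	phosphoglucomutase (alpha-D-glucose-1,6-bisphosphate-dependent)
6	Ligases
6.1	Forming carbon-oxygen bonds
6.1.1	Ligases forming aminoacyl-tRNA and related compounds
6.1.1.1	tyrosine--tRNA ligase
6.3	Forming carbon-nitrogen bonds
6.3.4	Other carbon-nitrogen ligases
6.3.4.14	biotin carboxylase
6.4	Forming carbon-carbon bonds
6.4.1	Ligases that form carbon-carbon bonds
6.4.1.1	pyruvate carboxylase
6.4.1.2	acetyl-CoA carboxylase
6.4.1.7	2-oxoglutarate carboxylase
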