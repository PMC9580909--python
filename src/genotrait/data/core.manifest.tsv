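#genotrait-manifest	v1
#hmm_name	trusted_cutoff	cross_refs	substrates
narG	50.0	KO:K00370,EC:1.7.5.1
narH	50.0	KO:K00371
narI	50.0	KO:K00374
napA	50.0	KO:K02567
napB	50.0	KO:K02568
nirS	50.0	KO:K15864,EC:1.7.2.1
nirK	50.0	KO:K00368,EC:1.7.2.1
norB	50.0	KO:K04561
norC	50.0	KO:K02305
norV	50.0	KO:K12264
norW	50.0	KO:K12265
nosZ	50.0	KO:K00376,EC:1.7.2.4
glcA	50.0	TC:3.A.1.2	glucose:monosaccharides
glcB	50.0	TC:3.A.1.2	glucose:monosaccharides
fruA	50.0	TC:4.A.2.1	fructose:monosaccharides
xylE	50.0	TC:2.A.1.1	xylose:monosaccharides
cebE	50.0	TC:3.A.1.1	cellobiose:oligosaccharides
cebF	50.0	TC:3.A.1.1	cellobiose:oligosaccharides
malE	50.0	TC:3.A.1.1	maltose:oligosaccharides
otsA	50.0	KO:K00697
otsB	50.0	KO:K01087
treS	50.0	KO:K05343
katE	50.0	KO:K03781
sodA	50.0	KO:K04564
rplA	50.0	KO:K02863,RIBO
rplB	50.0	KO:K02886,RIBO
rplC	50.0	KO:K02906,RIBO
rplD	50.0	KO:K02926,RIBO
rplE	50.0	KO:K02931,RIBO
rplF	50.0	KO:K02933,RIBO
rpsA	50.0	KO:K02945,RIBO
rpsB	50.0	KO:K02967,RIBO
rpsC	50.0	KO:K02982,RIBO
rpsD	50.0	KO:K02986,RIBO
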