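gene_id	role	category	ko_ids
der	RBF	GTPase	K03977
obgE	RBF	GTPase	K03979
era	RBF	GTPase	K03595
engB	RBF	GTPase	K03978
ysxC	RBF	GTPase	
rsgA	RBF	GTPase	K06949
rbgA	RBF	GTPase	K14540
hflX	RBF	GTPase	K03665
lepA	RBF	GTPase	K03596
bipA	RBF	GTPase	K06207
ychF	RBF	GTPase	K06942
groEL	RBF	chaperone	K04077
groES	RBF	chaperone	K04078
dnaK	RBF	chaperone	K04043
dnaJ	RBF	chaperone	K03686
grpE	RBF	chaperone	K03687
deaD	RBF	helicase	K05592
srmB	RBF	helicase	K05590
dbpA	RBF	helicase	K05591
rhlB	RBF	helicase	K03732
rhlE	RBF	helicase	K11927
rnc	RBF	ribonuclease	K03685
rne	RBF	ribonuclease	K08300
rng	RBF	ribonuclease	K08301
rnj	RBF	ribonuclease	K12574
rnb	RBF	ribonuclease	K01147
rnr	RBF	ribonuclease	K12573
rnt	RBF	ribonuclease	K03683
rph	RBF	ribonuclease	K00989
rnmV	RBF	ribonuclease	K13288
pnp	RBF	ribonuclease	K00962
ybeY	RBF	ribonuclease	K07042
yqgF	RBF	ribonuclease	K07447
fau-1	RBF	ribonuclease	
rbfA	RBF	maturation	K02834
rimM	RBF	maturation	K02860
rimP	RBF	maturation	K09748
rsfS	RBF	maturation	K09710
yjgA	RBF	maturation	K09889
rel	RBF	other	K00951
yhbH	RBF	other	K05808
yheS	RBF	other	K06158
yfiA	RBF	other	K05809
rmf	RBF	other	K03812
rsmA	RBF	modification	K02528
rsmB	RBF	modification	K03500
rsmC	RBF	modification	K00564
rsmD	RBF	modification	K08316
rsmE	RBF	modification	K09761
rsmF	RBF	modification	K11392
rsmG	RBF	modification	K03501
rsmH	RBF	modification	K03438
rsmI	RBF	modification	K07056
rsmJ	RBF	modification	K09791
rlmA	RBF	modification	K00563
rlmB	RBF	modification	K03218
rlmC	RBF	modification	K06968
rlmD	RBF	modification	K03215
rlmE	RBF	modification	K02427
rlmF	RBF	modification	K06969
rlmG	RBF	modification	K11391
rlmH	RBF	modification	K00783
rlmI	RBF	modification	K06971
rlmJ	RBF	modification	K07115
rlmK	RBF	modification	K12297
rlmL	RBF	modification	K16868
rlmM	RBF	modification	K06970
rlmN	RBF	modification	K06941
rsuA	RBF	modification	K06183
rluA	RBF	modification	K06177
rluB	RBF	modification	K06178
rluC	RBF	modification	K06179
rluD	RBF	modification	K06180
rluE	RBF	modification	K06181
rluF	RBF	modification	K06182
tsaB	RBF	modification	K14742
tsaC	RBF	modification	K07566
tsaD	RBF	modification	K01409
tsaE	RBF	modification	K06925
miaA	RBF	modification	K00791
miaB	RBF	modification	K06168
truB	RBF	modification	K03177
rimI	RBF	modification	K03789
rimJ	RBF	modification	K03790
rimL	RBF	modification	K03817
rimO	RBF	modification	K15865
tlyA	RBF	modification	K06442
mnmA	RBF	modification	K00566
mnmE	RBF	modification	K03650
mnmG	RBF	modification	K03495
trmA	RBF	modification	K00557
trmB	RBF	modification	K03439
trmD	RBF	modification	K00554
trmH	RBF	modification	K03437
trmJ	RBF	modification	K15396
trmL	RBF	modification	K03216
queA	RBF	modification	K07568
epmA	RBF	modification	K04568
epmB	RBF	modification	K19810
dusB	RBF	modification	K05540
rpsA	RP	other	
rpsB	RP	other	
rpsC	RP	other	
rpsD	RP	other	
rpsE	RP	other	
rpsF	RP	other	
rpsG	RP	other	
rpsH	RP	other	
rpsI	RP	other	
rpsJ	RP	other	
rpsK	RP	other	
rpsL	RP	other	
rpsM	RP	other	
rpsN	RP	other	
rpsO	RP	other	
rpsP	RP	other	
rpsQ	RP	other	
rpsR	RP	other	
rpsS	RP	other	
rpsT	RP	other	
rpsU	RP	other	
rplA	RP	other	
rplB	RP	other	
rplC	RP	other	
rplD	RP	other	
rplE	RP	other	
rplF	RP	other	
rplI	RP	other	
rplJ	RP	other	
rplK	RP	other	
rplL	RP	other	
rplM	RP	other	
rplN	RP	other	
rplO	RP	other	
rplP	RP	other	
rplQ	RP	other	
rplR	RP	other	
rplS	RP	other	
rplT	RP	other	
rplU	RP	other	
rplV	RP	other	
rplW	RP	other	
rplX	RP	other	
rplY	RP	other	
rpmA	RP	other	
rpmB	RP	other	
rpmC	RP	other	
rpmD	RP	other	
rpmE	RP	other	
rpmF	RP	other	
rpmG	RP	other	
rpmH	RP	other	
rpmI	RP	other	
rpmJ	RP	other	
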