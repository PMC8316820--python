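# Canonical collagen peptide-marker reference panel for eastern African
# archaeofauna ZooMS. Masses are nominal singly-protonated peptide masses
# (Da, [M+H]+), as conventionally printed as integers in ZooMS reference
# tables; matching always uses a tolerance (default below).
#
# Cell grammar: mass(";"mass)* — a "?"-suffixed mass is present in the
# underlying LC-MS/MS data but is not suitable for species identification
# (never used as supporting evidence); "—" or empty = the taxon lacks that
# marker region. Hydroxylation pairs (two masses ~16 Da apart) share a cell.
#
# Region "COL1a2 705-738" is an inferred label: the trailing hydroxylation
# pair (2843–2899 family) precedes the COL1a2 757-789 pair in every row but
# carries no printed region label of its own.
#
#! tolerance	0.5
#! common	1105	1427	1580	1648	2131	2792	2883	2899
#! tentative	Philantomba monticola	Eretmochelys imbricata	Dermochelys coriacea
#! inferred-region	COL1a2 705-738
#! inferred-cell	Bos spp.	A2 889
#! inferred-cell	Eretmochelys imbricata	COL1a2 757-789
#! inferred-cell	Dermochelys coriacea	COL1a2 757-789
taxon	COL1a1 507-518	COL1a2 978-990	COL1A2 375	COL1a2 484-498	A2 889	COL1a2 502-519	COL1a2 292-309	COL1a2 793-816	COL1a2 454-483	COL1a1 585-617	COL1a2 705-738	COL1a2 757-789
Neotragus moschatus	1105	1180;1196	1182?	2056?;2072?	1427	1532	1580	1648	2131	2792	2883;2899	3017?;3033
Bos spp.	1105	1192;1208	—	—	1427	1532	1580	1648	2131	2792	2853;2869	3017;3033
Ovis aries	1105	1180;1196	1154	2028;2044	1427	—	1580	1648	2131	2792	2883;2899	3017?;3033
Capra hircus	1105	1180;1196	1154	2028;2044	1427	—	1580	1648	2131	2792	2883;2899	3077;3093
Cephalophus spp.	1105	1192;1208	1154	2028;2044	1427	1574	1580	1648	2131	2792	2853;2869	3043;3059
cf. Philantomba monticola	1105	1192;1208	1154	2028;2044	1427	1560?	1580	1648	2131	2792	2883;2899	3043;3059
Canidae	1105	1210;1226	—	—	1453	—	1566	1649	2131	2820	2853;2869	2983;2999
Cercopithecinae	1105	1219;1235	—	—	1427	—	1580	1619	2115	2832	2883;2899	2958;2974
Eretmochelys imbricata	1220	—	—	—	1443	—	1459	1572	—	2790	2843;2859	2899;3007
Dermochelys coriacea	1136	—	—	—	1453	—	1459	1572	—	—	2854;2869	2899;3007
Felidae	1105	1207;1223	—	—	1453	—	1566	1609	2163	2820	2853;2869	2983;2999
Suidae	1105	1180;1196	—	—	1427	—	1550	1648	2131	2820	2883;2899	3017;3033
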