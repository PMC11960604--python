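roi_id	roi_name	hemisphere	volume_mm3
1001	bankssts	lh	2500
1002	caudalanteriorcingulate	lh	2000
1003	caudalmiddlefrontal	lh	6500
1004	cuneus	lh	3000
1005	entorhinal	lh	1900
1006	fusiform	lh	9500
1007	inferiorparietal	lh	13500
1008	inferiortemporal	lh	10500
1009	isthmuscingulate	lh	2700
1010	lateraloccipital	lh	11000
1011	lateralorbitofrontal	lh	7500
1012	lingual	lh	6500
1013	medialorbitofrontal	lh	5000
1014	middletemporal	lh	10500
1015	parahippocampal	lh	2200
1016	paracentral	lh	3500
1017	parsopercularis	lh	4500
1018	parsorbitalis	lh	2200
1019	parstriangularis	lh	3800
1020	pericalcarine	lh	2200
1021	postcentral	lh	10000
1022	posteriorcingulate	lh	3500
1023	precentral	lh	13000
1024	precuneus	lh	10000
1025	rostralanteriorcingulate	lh	2500
1026	rostralmiddlefrontal	lh	16000
1027	superiorfrontal	lh	22000
1028	superiorparietal	lh	13000
1029	superiortemporal	lh	11500
1030	supramarginal	lh	10000
1031	frontalpole	lh	1000
1032	temporalpole	lh	2500
1033	transversetemporal	lh	1500
1034	insula	lh	7000
2001	bankssts	rh	2500
2002	caudalanteriorcingulate	rh	2000
2003	caudalmiddlefrontal	rh	6500
2004	cuneus	rh	3000
2005	entorhinal	rh	1900
2006	fusiform	rh	9500
2007	inferiorparietal	rh	13500
2008	inferiortemporal	rh	10500
2009	isthmuscingulate	rh	2700
2010	lateraloccipital	rh	11000
2011	lateralorbitofrontal	rh	7500
2012	lingual	rh	6500
2013	medialorbitofrontal	rh	5000
2014	middletemporal	rh	10500
2015	parahippocampal	rh	2200
2016	paracentral	rh	3500
2017	parsopercularis	rh	4500
2018	parsorbitalis	rh	2200
2019	parstriangularis	rh	3800
2020	pericalcarine	rh	2200
2021	postcentral	rh	10000
2022	posteriorcingulate	rh	3500
2023	precentral	rh	13000
2024	precuneus	rh	10000
2025	rostralanteriorcingulate	rh	2500
2026	rostralmiddlefrontal	rh	16000
2027	superiorfrontal	rh	22000
2028	superiorparietal	rh	13000
2029	superiortemporal	rh	11500
2030	supramarginal	rh	10000
2031	frontalpole	rh	1000
2032	temporalpole	rh	2500
2033	transversetemporal	rh	1500
2034	insula	rh	7000
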