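gene	chrom	start	end	n_markers	best_marker	best_p
SF3B1	2	198236697	198319771	318	rs6434928	1.5e-11
FOXP1	3	70983864	71653140	3431	rs7372960	1.2e-7
DLG2	11	83146055	85358314	13630	rs12294291	4.9e-7
VGLL4	3	11577540	11782242	1508	chr3_11689216_D	1.4e-5
ROBO1	3	78626387	79837059	6944	rs188858898	7.4e-5
AKAP5	14	64912216	64961221	253	rs1980520	0.00023
PALM2	9	112383067	112733756	2550	rs78341776	0.00033
SMAD2	18	45339465	45477517	719	rs189158823	0.00045
CAMK4	5	110539946	110840748	1685	rs117821127	0.00099
PRDM5	4	121595928	121864013	1951	chr4_121723039_I	0.0010
SMURF2	17	62520734	62678386	644	rs117024269	0.0014
CUL5	11	107859407	107998488	753	chr11_107977411_I	0.0022
ARSG/WIPI1	17	66235322	66473653	1395	rs149373128	0.0026
SPATA6	1	48741043	48957880	1306	rs146859685	0.0028
TSLP	5	110385777	110433722	291	rs79283270	0.011
MIA3	1	222771443	222861351	448	rs9441835	0.011
ALB	4	74249971	74307129	278	rs12651581	0.012
ADAMTS1	21	28188605	28237728	350	rs181607589	0.013
KRT18	12	53322654	53366685	270	rs113120949	0.014
FOXJ1	17	74112414	74157380	267	rs117235875	0.014
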