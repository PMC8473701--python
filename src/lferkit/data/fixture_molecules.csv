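id,smiles,formula,sm,flex,n_c3,n_c4
methane,C,CH4,2.2,0.0,0,0
n-butane,CCCC,C4H10,7.0,1.0,0,0
n-pentane,CCCCC,C5H12,8.6,2.0,0,0
isobutane,CC(C)C,C4H10,6.8,0.0,1,0
neopentane,CC(C)(C)C,C5H12,8.0,0.0,0,1
cyclohexane,C1CCCCC1,C6H12,9.6,0.0,0,0
benzene,c1ccccc1,C6H6,7.8,0.0,0,0
toluene,Cc1ccccc1,C7H8,9.4,0.0,0,0
ethylbenzene,CCc1ccccc1,C8H10,11.0,0.5,0,0
propylbenzene,CCCc1ccccc1,C9H12,12.6,1.5,0,0
catechol,Oc1ccccc1O,C6H6O2,9.8,0.0,0,0
ethanol,CCO,C2H6O,4.8,0.0,0,0
1-propanol,CCCO,C3H8O,6.4,1.0,0,0
tert-butanol,CC(C)(C)O,C4H10O,7.4,0.0,0,1
diethyl ether,CCOCC,C4H10O,8.0,3.0,0,0
1-2-dimethoxyethane,COCCOC,C4H10O2,9.0,4.0,0,0
anisole,COc1ccccc1,C7H8O,10.4,0.0,0,0
acetamide,CC(N)=O,C2H5NO,5.5,0.0,0,0
N-methylacetamide,CNC(C)=O,C3H7NO,7.1,0.0,0,0
acetophenone,CC(=O)c1ccccc1,C8H8O,11.4,0.0,0,0
methyl acetate,COC(C)=O,C3H6O2,6.8,0.0,0,0
chloroform,ClC(Cl)Cl,CHCl3,6.5,0.0,1,0
bromoethane,CCBr,C2H5Br,5.7,0.0,0,0
iodomethane,CI,CH3I,4.5,0.0,0,0
2-fluoropropane,CC(F)C,C3H7F,5.7,0.0,0,0
trifluoromethylbenzene,FC(F)(F)c1ccccc1,C7H5F3,10.3,0.0,0,0
biphenyl,c1ccc(-c2ccccc2)cc1,C12H10,15.0,0.0,0,0
aniline,Nc1ccccc1,C6H7N,9.1,0.0,0,0
dimethyl sulfide,CSC,C2H6S,5.8,0.0,0,0
n-propylamine,CCCN,C3H9N,6.7,1.0,0,0
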