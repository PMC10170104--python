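name,polarity,mz,rt_rp,rt_hilic,detected_rp,detected_hilic,compound_subclass,role,spike_group,hmdb_id,kegg_id
2-Aminobenzoic acid,POS,138.055,30,447,true,true,Benzoic acids,MOINT,,HMDB0000446,C00108
3-Dehydroxycarnitine,POS,146.118,28,567,true,false,Fatty acids,MOINT,,HMDB0001161,C01181
3-Ketocholesterol,POS,385.347,588,74,true,false,Cholestane steroids,MOINT,,,
3-Methoxytyrosine,POS,212.092,58,,true,false,Amino acids,MOINT,,HMDB0001434,
Adenosine,POS,268.104,59,298,true,true,Purine nucleosides,MOINT,,HMDB0000050,C00212
Aminoadipic acid,POS,162.076,36,461,true,false,Amino acids,MOINT,,HMDB0000510,C00956
Arginine,POS,175.119,23,556,true,true,Amino acids,MOINT,,HMDB0000517,C00062
Asparagine,POS,133.061,23,517,true,false,Amino acids,MOINT,,HMDB0000168,C00152
Aspartic acid,POS,134.045,25,542,true,false,Amino acids,MOINT,,HMDB0000191,C00049
Creatine,POS,132.077,25,511,true,true,Amino acids,MOINT,,HMDB0000064,C00300
Cytidine,POS,244.093,27,414,true,true,Pyrimidine nucleosides,MOINT,,HMDB0000089,C00475
Dimethylarginine,POS,203.150,23,554,false,true,Amino acids,MOINT,,HMDB0001539,
Glutamic acid,POS,148.060,25,538,true,true,Amino acids,MOINT,,HMDB0000148,C00025
Glutamine,POS,147.076,23,515,true,true,Amino acids,MOINT,,HMDB0000641,C00064
Glycerophosphocholine,POS,258.110,24,540,true,true,Glycerophosphocholines,MOINT,,HMDB0000086,C00670
Histidine,POS,156.077,21,513,true,false,Amino acids,MOINT,,HMDB0000177,C00135
Hypoxanthine,POS,137.046,35,303,true,true,Purines,MOINT,,HMDB0000157,C00262
Inosine,POS,269.088,56,361,true,true,Purine nucleosides,MOINT,,HMDB0000195,C00294
Inosinic acid,POS,349.054,29,543,true,true,Purine ribonucleotides,MOINT,,HMDB0000175,C00130
Leucine,POS,132.102,41,456,true,true,Amino acids,MOINT,,HMDB0000687,C00123
Lysine,POS,147.113,22,562,true,true,Amino acids,MOINT,,HMDB0000182,C00047
Methionine,POS,150.058,32,468,true,true,Amino acids,MOINT,,HMDB0000696,C00073
"N6,N6,N6-trimethyl-l-lysine",POS,189.160,22,602,true,false,Amino acids,MOINT,,HMDB0001325,C03793
Nicotinamide,POS,123.055,45,170,true,false,Pyridinecarboxylic acids,MOINT,,HMDB0001406,C00153
N-Palmitoyl-d-Sphingosine,POS,538.519,602,85,true,false,Ceramides,MOINT,,HMDB0004949,C00195
Phenylalanine,POS,166.086,77,448,true,false,Amino acids,MOINT,,HMDB0000159,C00079
Pipecolic acid,POS,130.086,23,192,true,false,Amino acids,MOINT,,HMDB0000070,C00408
Propionylcarnitine,POS,218.139,288,484,true,true,Fatty acid esters,MOINT,,HMDB0000824,C03017
Stearoylethanolamide,POS,328.322,506,91,true,false,Amines,MOINT,,HMDB0013078,
Threonine,POS,120.066,24,509,true,false,Amino acids,MOINT,,HMDB0000167,C00188
Tryptophan,POS,205.097,139,452,true,true,Indolyl carboxylic acids,MOINT,,HMDB0000929,C00078
Tyrosine,POS,182.081,35,475,true,true,Amino acids,MOINT,,HMDB0000158,C00082
Uridine,POS,245.077,31,251,true,false,Pyrimidine nucleosides,MOINT,,HMDB0000296,C00299
Xanthine,POS,153.041,37,269,true,true,Purines,MOINT,,HMDB0000292,C00385
Aminoadipic acid,NEG,160.062,36,461,false,true,Amino acids,MOINT,,HMDB0000510,C00956
Arginine,NEG,173.104,23,556,false,true,Amino acids,MOINT,,HMDB0000517,C00062
Cytidine,NEG,242.078,27,414,false,true,Pyrimidine nucleosides,MOINT,,HMDB0000089,C00475
Glucose,NEG,179.056,26,475,true,false,Carbohydrates,MOINT,,HMDB0000122,C00031
Glutamic acid,NEG,146.050,25,538,true,true,Amino acids,MOINT,,HMDB0000148,C00025
Glutamine,NEG,145.062,23,515,true,true,Amino acids,MOINT,,HMDB0000641,C00064
Histidine,NEG,154.062,21,513,true,false,Amino acids,MOINT,,HMDB0000177,C00135
Hypoxanthine,NEG,135.031,35,303,true,true,Purines,MOINT,,HMDB0000157,C00262
Inosine,NEG,267.073,56,361,true,true,Purine nucleosides,MOINT,,HMDB0000195,C00294
Inosinic acid,NEG,347.040,29,543,true,true,Purine ribonucleotides,MOINT,,HMDB0000175,C00130
Methionine,NEG,148.044,32,468,true,true,Amino acids,MOINT,,HMDB0000696,C00073
Phenylalanine,NEG,164.072,77,448,true,true,Amino acids,MOINT,,HMDB0000159,C00079
Tryptophan,NEG,203.083,139,452,true,false,Indolyl carboxylic acids,MOINT,,HMDB0000929,C00078
Tyrosine,NEG,180.066,35,475,true,true,Amino acids,MOINT,,HMDB0000158,C00082
Uridine,NEG,245.078,31,262,false,true,Pyrimidine nucleosides,MOINT,,HMDB0000296,C00299
Xanthine,NEG,151.026,37,269,true,true,Purines,MOINT,,HMDB0000292,C00385
Tryptophan-d5,POS,210.121,140,452,true,true,Amino acids,IS,1,,
Palmitic acid-d31,NEG,286.427,610,80,true,false,Fatty acids,IS,1,,
Glucose-d7,NEG,186.100,26,475,true,false,Carbohydrates,IS,1,,
Trimipramine-d3,POS,298.236,330,150,true,true,Dibenzazepines,IS,2,,
Glibenclamide,POS,494.151,420,120,true,true,Sulfonylureas,IS,2,,
Bisoprolol-d5,POS,331.264,250,210,true,true,Phenol ethers,IS,3,,
Telmisartan-d7,POS,522.288,400,130,true,true,Benzimidazoles,IS,3,,
Hydrochlorothiazide,NEG,295.957,180,220,true,true,Benzothiadiazines,IS,3,,
Furosemide,NEG,329.000,300,200,true,true,Sulfonamides,IS,3,,
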