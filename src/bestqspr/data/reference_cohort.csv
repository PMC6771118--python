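proband_id,sex,age_years,exon,nucleotide_change,amino_acid_change,second_amino_acid_change,allele_state,family_study,stage_le,stage_re,bcva_le,bcva_re
P1,M,50,ex2,c.5C>T,p.(Thr2Ile),NA,HET,false,5,5,0.1,0.4
P2,F,42,ex2,c.11C>T,p.(Thr4Ile),NA,HET,false,2,2,0,0
P3,F,13,ex2,c.11C>T,p.(Thr4Ile),NA,HET,true,1,1,0.1,0.1
P4,M,27,ex2,c.26T>G,p.(Val9Gly),NA,HET,true,2,2,0,0.6
P5,F,34,ex2,c.44G>A,p.(Gly15Asp),NA,HET,false,NA,NA,NA,NA
P6,M,22,ex2,c.44G>A,p.(Gly15Asp),NA,HET,false,3,4,0,0.2
P7,F,13,ex2,c.44G>A,p.(Gly15Asp),NA,HET,false,0,3,0,0.22
P8,M,56,ex2,c.47C>T,p.(Ser16Phe),NA,HET,true,2,2,0.1,0.7
P9,F,23,ex2,c.74G>A,p.(Arg25Gln),NA,HET,false,4,2,0.5,0
P10,F,47,ex1,c.80G>C,p.(Ser27Thr),NA,HET,false,3,4,0.1,0.2
P11,F,55,ex2,c.80G>C,p.(Ser27Thr),NA,HET,true,2,2,NA,NA
P12,F,52,ex2,c.80G>C,p.(Ser27Thr),NA,HET,false,3,3,0.7,1
P13,M,10,ex2,c.86A>G,p.(Tyr29Cys),NA,HET,true,4,4,0,0
P14,F,27,ex4,c.274C>T,p.(Arg92Cys),NA,HOM,false,NA,NA,NA,NA
P15,M,42,ex4,c.278G>C,p.(Trp93Ser),NA,HET,false,NA,NA,NA,NA
P16,M,70,ex4,c.301C>A,p.(Pro101Thr),NA,HET,true,4,3,0.5,0
P17,M,26,ex4,c.324C>G,p.(Ser108Arg),NA,HET,false,2,2,0.1,1
P18,M,46,ex5,c.535A>G,p.(Asn179Asp),NA,HET,false,1,2,0.3,0.3
P19,F,13,ex5,c.544T>C,p.(Trp182Arg),NA,HET,false,4,4,NA,NA
P20,M,19,ex5,c.598C>T,p.(Arg200*),p.(Ala243Glu),HET,true,NA,NA,NA,NA
P21,F,25,ex6,c.652C>T,p.(Arg218Cys),NA,HET,true,2,2,0.1,0
P22,F,13,ex6,c.652C>T,p.(Arg218Cys),NA,HET,false,0,3,0,0.17
P23,M,14,ex6,c.652C>T,p.(Arg218Cys),NA,HET,false,2,2,0.4,0
P24,M,42,ex6,c.652C>A,p.(Arg218Ser),NA,HET,false,3,3,0.5,0.4
P25,M,54,ex5,c.695T>A,p.(Ile232Asn),NA,HET,false,3,3,0.6,0.8
P26,M,17,ex6,c.703G>T,p.(Val235Leu),NA,HET,false,3,3,0.1,0.1
P27,F,51,ex7,c.727G>A,p.(Ala243Thr),NA,HET,true,2,2,1,1
P28,M,49,ex7,c.728C>T,p.(Ala243Val),NA,HET,false,3,3,0.1,0
P29,F,43,ex7,c.728C>T,p.(Ala243Val),NA,HET,true,3,2,0.2,0.2
P30,F,50,ex7,c.728C>T,p.(Ala243Val),NA,HET,true,NA,NA,NA,NA
P31,M,9,ex8,c.874G>C,p.(Glu292Gln),NA,HET,true,2,2,1,1
P32,M,39,ex8,c.888C>G,p.(Asn296Lys),NA,HET,false,3,3,0.1,0.3
P33,F,41,ex8,c.888C>A,p.(Asn296Lys),NA,HET,false,2,2,0.3,0.3
P34,M,10,ex8,c.893T>G,p.(Phe298Cys),NA,HET,false,NA,NA,NA,NA
P35,M,53,ex8,c.893T>G,p.(Phe298Cys),NA,HET,false,NA,NA,NA,NA
P36,M,21,ex8,c.903T>G,p.(Asp301Glu),NA,HET,true,NA,NA,0,0.6
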