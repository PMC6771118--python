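point_id,proband_ids,amino_acid_change,mean_bdsi,dde_dim,dde_cabin,pmva,location
P1,P1,p.(Thr2Ile),11.90,-23,-91,0.24,interface:B;near-K-site:B;near-Ca-site:B
P2-P3,P2;P3,p.(Thr4Ile),3.55,-13,9,0.19,interface:B;interface:E;near-K-site:B;near-Ca-site:B
P4,P4,p.(Val9Gly),17.60,-34,62,0.29,interface:B;near-K-site:B;near-Ca-site:B
P5-P7,P5;P6;P7,p.(Gly15Asp),7.10,-1,4,0.13,interface:B;near-K-site:B;near-Ca-site:B
P8,P8,p.(Ser16Phe),17.60,50,-19,0.37,interface:B;near-K-site:B;near-Ca-site:B
P9,P9,p.(Arg25Gln),15.30,11,-49,0.18,membrane-facing;near-K-site:B;near-Ca-site:B
P10-P12,P10;P11;P12,p.(Ser27Thr),23.10,-71,16,0.47,interface:B;near-K-site:B;near-Ca-site:B
P13,P13,p.(Tyr29Cys),0.00,-13,-3,0.19,interface:B;near-K-site:B;near-Ca-site:B
P14,P14,p.(Arg92Cys),NA,12,-23,0.19,pore-lining;near-Ca-site:A;interface:E
P15,P15,p.(Trp93Ser),NA,12,-15,0.19,pore-lining;near-Ca-site:A;interface:B
P16,P16,p.(Pro101Thr),9.50,-17,-24,0.21,pore-lining;interface:B
P17,P17,p.(Ser108Arg),32.60,96,-7,0.59,interface:B
P18,P18,p.(Asn179Asp),15.30,23,-50,0.24,interface:D;interface:E
P19,P19,p.(Trp182Arg),NA,26,25,0.25,interface:E
P20,P20,p.(Arg200*),NA,NA,NA,NA,other
P21-P23,P21;P22;P23,p.(Arg218Cys),7.60,-1,25,0.13,interface:E;near-Cl-site
P24,P24,p.(Arg218Ser),23.40,32,55,0.28,interface:E;near-Cl-site
P25,P25,p.(Ile232Asn),31.40,21,-46,0.23,interface:E;pore-lining;near-Ca-site:A
P26,P26,p.(Val235Leu),6.50,6,7,0.16,interface:E
P27,P27,p.(Ala243Thr),46.20,5,-47,0.15,interface:E
P28-P30,P28;P29;P30,p.(Ala243Val),6.50,-7,-48,0.16,interface:E
P31,P31,p.(Glu292Gln),70.30,-14,42,0.20,near-Ca-site:A;near-K-site:A;interface:E
P32-P33,P32;P33,p.(Asn296Lys),12.85,-17,80,0.21,near-Ca-site:A;interface:E
P34-P35,P34;P35,p.(Phe298Cys),NA,26,-35,0.25,near-Ca-site:A;interface:E
P36,P36,p.(Asp301Glu),18.70,-60,-7,0.42,near-Ca-site:A;interface:E;membrane-facing
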