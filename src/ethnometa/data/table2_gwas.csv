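snp_id,gene,chromosome,reference,or_gwas,ci_low,ci_high,raf,n_cases
rs4607103,ADAMTS9,3,zeggini_2008,1.09,1.06,1.12,0.50,2307
rs12779790,CDC123,10,zeggini_2008,1.11,1.07,1.14,0.14,4049
rs864745,JAZF1,7,zeggini_2008,1.10,1.07,1.13,0.71,4055
rs2237895,KCNQ1,11,tsai_2010,1.29,1.19,1.40,0.42,1424
rs2191349,DGKB-TMEM195,7,dupuis_2010,1.06,1.04,1.08,0.61,1632
rs1799884,GCK,7,dupuis_2010,1.07,1.05,1.10,0.14,1670
rs780094,GCKR,7,dupuis_2010,1.06,1.04,1.08,0.76,4055
rs5219,KCNJ11,11,scott_2007,1.14,1.10,1.19,0.37,5643
rs340874,PROX1,1,dupuis_2010,1.07,1.05,1.09,0.58,1626
rs10830963,MTNR1B,11,dupuis_2010,1.09,1.06,1.12,0.40,3475
rs7578597,THADA,2,zeggini_2008,1.15,1.10,1.20,0.86,4090
rs231362,KCNQ1,11,voight_2010,1.08,1.06,1.10,0.75,3052
rs10923931,NOTCH2,1,zeggini_2008,1.13,1.08,1.17,0.21,4035
rs7961581,TSPAN8,12,zeggini_2008,1.09,1.06,1.12,0.33,3977
rs10010131,WFS1,4,voight_2010,1.13,1.08,1.18,0.72,5022
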