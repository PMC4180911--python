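study_id,population,snp_id,gene,chromosome,risk_allele,other_allele,n_cases,n_controls,raf_cases,raf_controls,raf_combined,or_point,ci_low,ci_high,ld_group
saxena_2013,south_asian,rs9552911,SGCG,13,G,,2620,4284,,,0.08,1.49,1.30,1.72,
kooner_2011,south_asian,rs2028299,AP3S2,15,C,,18731,39856,,,0.31,1.10,1.07,1.13,
tabassum_2013,south_asian,rs2028299,AP3S2,15,C,,1256,1209,,,0.30,1.10,0.96,1.25,
kooner_2011,south_asian,rs16861329,ST6GAL1,3,C,,18731,39856,,,0.75,1.09,1.06,1.12,
tabassum_2013,south_asian,rs16861329,ST6GAL1,3,C,,1256,1209,,,0.75,1.14,0.99,1.31,
sim_2011,south_asian,rs1048886,C6orf57,6,G,,977,1169,,,0.18,1.54,1.32,1.80,
kooner_2011,south_asian,rs3923113,GRB14,2,A,,18731,39856,,,0.74,1.09,1.06,1.13,
tabassum_2013,south_asian,rs3923113,GRB14,2,A,,1256,1209,,,0.76,1.15,0.99,1.33,
kooner_2011,south_asian,rs7178572,HMG20A,15,G,,18731,39856,,,0.52,1.09,1.06,1.12,
tabassum_2013,south_asian,rs7178572,HMG20A,15,G,,1256,1209,,,0.51,1.15,1.02,1.30,
kooner_2011,south_asian,rs4812829,HNF4A,20,A,,18731,39856,,,0.29,1.09,1.06,1.12,
tabassum_2013,south_asian,rs4812829,HNF4A,20,A,,1256,1209,,,0.28,1.15,1.02,1.30,
kooner_2011,south_asian,rs1802295,VPS26A,10,T,,18731,39856,,,0.26,1.08,1.05,1.12,
tabassum_2013,south_asian,rs1802295,VPS26A,10,T,,1256,1209,,,0.27,1.09,0.95,1.25,
tabassum_2013,south_asian,rs6723108,TMEM163,2,T,,1256,1209,,,0.87,1.31,1.20,1.44,
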