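study_id,population,snp_id,gene,chromosome,risk_allele,other_allele,n_cases,n_controls,raf_cases,raf_controls,raf_combined,or_point,ci_low,ci_high,ld_group
diagram,white_european,rs2028299,AP3S2,15,C,,9580,53810,,,0.26,1.04,1.00,1.09,
diagram,white_european,rs16861329,ST6GAL1,3,C,,6201,48359,,,0.87,1.03,0.97,1.09,
diagram,white_european,rs1048886,C6orf57,6,G,,12171,56862,,,0.17,1.01,0.97,1.06,
diagram,white_european,rs3923113,GRB14,2,A,,9580,53810,,,0.61,1.04,1.00,1.08,
diagram,white_european,rs7178572,HMG20A,15,G,,22669,58119,,,0.68,1.08,1.05,1.10,
diagram,white_european,rs4812829,HNF4A,20,A,,9580,53810,,,0.16,1.07,1.02,1.12,
diagram,white_european,rs1802295,VPS26A,10,T,,12171,56862,,,0.27,1.02,0.98,1.06,
diagram,white_european,rs6723108,TMEM163,2,T,,9580,53810,,,0.62,1.01,0.97,1.04,
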