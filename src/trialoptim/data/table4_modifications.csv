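trial_id,phase,from_version,to_version,target_es_before,target_es_after,total_n_change_fraction,reason,induced_by,observed_es
E1,ethics,1,2,1.03,1.03,0.00,Clarification of parameters,REC,0.50
E2,ethics,1,2,1.03,1.03,0.00,Clarification of parameters,REC,0.69
E3,ethics,1,2,0.83,0.59,0.00,Correction error,REC,0.83
E4,ethics,1,2,0.70,0.61,0.30,"Correction error, clarification and substantiation of chosen parameters",REC,0.77
E4,ethics,2,3,0.61,0.81,-0.42,Correction error,REC,0.77
E4,ethics,3,4,0.81,0.75,0.14,Correction error,REC,0.77
E5,ethics,1,2,0.81,0.70,0.50,Correction error,REC,0.58
E6,ethics,1,2,0.39,0.39,-0.18,Correction error,REC,0.37
E7,ethics,1,2,0.33,0.44,-0.42,Change in primary outcome measure and chosen parameters,investigator,0.42
A1,amendment,1,2,0.42,0.42,0.15,Adjustment for dropout,investigator,0.03
A2,amendment,1,2,0.72,0.72,-0.11,Adjustment for dropout,investigator,0.22
A3,amendment,1,2,0.60,0.51,0.43,"Decrease of target effect size based on external evidence, increase power for secondary outcomes, adjustment for dropout",investigator,0.47
A4,amendment,1,2,0.40,0.43,0.13,"Increase of target effect size based on external evidence, increase power",investigator,0.54
A5,amendment,1,2,0.50,0.68,-0.43,Preplanned interim analysis for sample size recalculation,investigator,0.44
A6,amendment,1,2,0.77,0.57,0.60,Preplanned interim analysis for sample size recalculation,investigator,0.55
A6,amendment,2,3,0.57,0.61,0.12,Change of primary outcome and increase of power,investigator,0.55
A7,amendment,1,2,0.95,0.86,0.06,Change of primary outcome,investigator,0.07
A8,amendment,1,2,0.40,0.55,-0.47,Change of primary outcome,investigator,1.02
A9,amendment,1,2,0.51,0.51,-0.33,"Increase of alpha and power, change from confirmatory to exploratory aim",investigator,0.45
A10,amendment,1,2,0.50,0.50,-0.52,Introduction of crossover arm to account for recruitment failure,investigator,0.06
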