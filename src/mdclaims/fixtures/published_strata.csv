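algorithm,target,tp,flagged,printed_pct,printed_precision
ANY_MD_1CODE,any_md,260,537,48.4,1
ANY_MD_1CODE,dbmd,136,537,25.3,1
CODE_35921_1CODE,myotonic,46,58,79.3,1
ANY_MD_ROBUST,any_md,224,378,59.3,1
ANY_MD_ROBUST,dbmd,118,378,31.2,1
MALE_LE18_3591_ROBUST,any_md,77,93,82.8,1
MALE_LE18_3591_ROBUST,dbmd,51,80,63.8,1
NEURO_CODED_3591,any_md,49,59,83.1,1
NEURO_CODED_3591,dbmd,33,50,66,0
OTHERSPEC_CODED_3591,any_md,77,93,82.8,1
OTHERSPEC_CODED_3591,dbmd,51,80,64,0
STEROID_3591,dbmd,22,35,62.9,1
TIER_3591_1VISITS,any_md,82,105,78.1,1
TIER_3591_3VISITS,any_md,75,87,86.2,1
TIER_3591_1VISITS,dbmd,54,90,60.0,1
TIER_3591_3VISITS,dbmd,49,74,66.2,1
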