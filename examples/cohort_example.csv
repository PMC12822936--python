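patient_id,depth,osteomyelitis_or_abscess,gangrene,infection_idsa,ischemia_grade,neuropathy_grade,edema_grade,site_region,se_location,se_topography,se_zones,area_cm2,healing_phase,major_amputation,minor_amputation,inpatient,follow_up_months
P01,intact,false,none,none,none,none,none,forefoot,phalangeal,dorsal_or_plantar,one,0.0,epithelialization,false,false,false,12.0
P02,superficial,false,none,none,none,none,none,forefoot,phalangeal,dorsal_or_plantar,one,1.5,epithelialization,false,false,false,24.0
P03,tendon_capsule,false,none,none,none,diminished,none,midfoot,metatarsal,lateral_or_medial,one,2.0,granulation,false,false,false,18.0
P04,bone_joint,true,none,mild,none,lops,perilesional,forefoot,phalangeal,dorsal_or_plantar,one,4.0,inflammatory,false,true,true,9.0
P05,superficial,false,localized,moderate,moderate,lops,unilateral,forefoot,phalangeal,lateral_or_medial,two,8.0,inflammatory,false,true,true,8.0
P06,bone_joint,true,extensive,severe,severe,charcot,bilateral,hindfoot,tarsal,two_or_more,whole_foot,50.0,inflammatory,true,false,true,6.0
P07,bone_joint,false,none,moderate,mild,lops,perilesional,forefoot,metatarsal,two_or_more,two,15.0,inflammatory,true,false,true,7.0
P08,tendon_capsule,false,none,mild,none,none,none,forefoot,phalangeal,dorsal_or_plantar,one,1.0,granulation,false,false,false,30.0
P09,superficial,false,none,none,moderate,none,none,midfoot,metatarsal,lateral_or_medial,one,0.8,epithelialization,false,false,false,12.0
P10,bone_joint,true,localized,severe,severe,diminished,unilateral,forefoot,tarsal,lateral_or_medial,two,42.0,inflammatory,true,false,true,6.5
P11,superficial,false,none,mild,mild,diminished,perilesional,hindfoot,tarsal,dorsal_or_plantar,one,1.5,granulation,false,false,false,20.0
P12,tendon_capsule,false,none,moderate,none,lops,bilateral,midfoot,metatarsal,two_or_more,two,12.0,granulation,false,true,true,10.0
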