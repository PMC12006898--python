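category,subgroup,n_total,mean_diff,ci_lower,ci_upper,ci_level,allocation
MAO-B inhibitor,Yes,115,-2.66,-4.87,-0.45,0.80,2:1
MAO-B inhibitor,No,201,-0.87,-2.69,0.94,0.80,2:1
Hoehn and Yahr stage,2,238,-2.55,-4.19,-0.9,0.80,2:1
Hoehn and Yahr stage,1,78,3.14,0.32,5.95,0.80,2:1
RBDSQ,>=5,85,-2.76,-5.78,0.25,0.80,2:1
RBDSQ,<5,230,-1.03,-2.63,0.57,0.80,2:1
Data-driven subphenotype,Diffuse malignant,59,-7.86,-12.9,-2.82,0.80,2:1
Data-driven subphenotype,Nondiffuse malignant,257,-0.77,-2.2,0.66,0.80,2:1
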