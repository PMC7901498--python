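code_id,terminology,description,category,source
R0001,READ,Heroin dependence,CLINICAL_DEFINITE,illustrative
R0002,READ,Opioid misuse,CLINICAL_DEFINITE,illustrative
R0003,READ,Opiate overdose,CLINICAL_DEFINITE,illustrative
R0004,READ,Injecting drug user,CLINICAL_PROBABLE,illustrative
R0005,READ,Misuse of Codeine tablets,CLINICAL_PROBABLE,illustrative
R0006,READ,Methadone drug level test,EXCLUDED,illustrative
S0001,SNOMED,Heroin dependence (disorder),CLINICAL_DEFINITE,illustrative
S0002,SNOMED,Opioid abuse (disorder),CLINICAL_DEFINITE,illustrative
S0003,SNOMED,History of injecting drug use,CLINICAL_PROBABLE,illustrative
P0001,PRODUCT,Methadone 1mg/ml oral solution,OAT_PRODUCT,illustrative
P0002,PRODUCT,Buprenorphine 8mg sublingual tablet,OAT_PRODUCT,illustrative
P0003,PRODUCT,Buprenorphine 5microgram/hour transdermal patch,EXCLUDED,illustrative
P0004,PRODUCT,Methadone 5mg/5ml oral solution,OAT_PRODUCT,illustrative
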