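pattern,system,sre_type,tier,role
7331*,ICD9_DX,PF,SPECIFICITY,EVENT
800*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
801*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
802*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
803*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
804*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
805*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
806*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
807*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
808*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
809*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
810*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
811*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
812*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
813*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
814*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
815*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
816*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
817*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
818*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
819*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
820*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
821*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
822*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
823*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
824*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
825*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
826*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
827*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
828*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
829*,ICD9_DX,PF,SENSITIVITY_EXT,EVENT
3369,ICD9_DX,SCC,SPECIFICITY,EVENT
63001,HCPCS,SCC,SPECIFICITY,EVENT
63003,HCPCS,SCC,SPECIFICITY,EVENT
63005,HCPCS,SCC,SPECIFICITY,EVENT
63011,HCPCS,SCC,SPECIFICITY,EVENT
63015,HCPCS,SCC,SPECIFICITY,EVENT
63016,HCPCS,SCC,SPECIFICITY,EVENT
63017,HCPCS,SCC,SPECIFICITY,EVENT
03091,ICD9_PX,SCC,SPECIFICITY,EVENT
7211,ICD9_DX,SCC,SENSITIVITY_EXT,EVENT
72141,ICD9_DX,SCC,SENSITIVITY_EXT,EVENT
72142,ICD9_DX,SCC,SENSITIVITY_EXT,EVENT
72191,ICD9_DX,SCC,SENSITIVITY_EXT,EVENT
7227*,ICD9_DX,SCC,SENSITIVITY_EXT,EVENT
63045,HCPCS,SCC,SENSITIVITY_EXT,EVENT
63046,HCPCS,SCC,SENSITIVITY_EXT,EVENT
63047,HCPCS,SCC,SENSITIVITY_EXT,EVENT
63048,HCPCS,SCC,SENSITIVITY_EXT,EVENT
9221,ICD9_PX,RAD,SPECIFICITY,EVENT
9222,ICD9_PX,RAD,SPECIFICITY,EVENT
9223,ICD9_PX,RAD,SPECIFICITY,EVENT
9224,ICD9_PX,RAD,SPECIFICITY,EVENT
9225,ICD9_PX,RAD,SPECIFICITY,EVENT
9226,ICD9_PX,RAD,SPECIFICITY,EVENT
9229,ICD9_PX,RAD,SPECIFICITY,EVENT
77402,HCPCS,RAD,SPECIFICITY,EVENT
77403,HCPCS,RAD,SPECIFICITY,EVENT
77404,HCPCS,RAD,SPECIFICITY,EVENT
77406,HCPCS,RAD,SPECIFICITY,EVENT
77407,HCPCS,RAD,SPECIFICITY,EVENT
77408,HCPCS,RAD,SPECIFICITY,EVENT
77409,HCPCS,RAD,SPECIFICITY,EVENT
77411,HCPCS,RAD,SPECIFICITY,EVENT
77412,HCPCS,RAD,SPECIFICITY,EVENT
77413,HCPCS,RAD,SPECIFICITY,EVENT
77414,HCPCS,RAD,SPECIFICITY,EVENT
77416,HCPCS,RAD,SPECIFICITY,EVENT
79101,HCPCS,RAD,SPECIFICITY,EVENT
A9600,HCPCS,RAD,SPECIFICITY,EVENT
A9604,HCPCS,RAD,SPECIFICITY,EVENT
A9605,HCPCS,RAD,SPECIFICITY,EVENT
77418,HCPCS,RAD,SENSITIVITY_EXT,EVENT
G0174,HCPCS,RAD,SENSITIVITY_EXT,EVENT
77371,HCPCS,RAD,SENSITIVITY_EXT,EVENT
77372,HCPCS,RAD,SENSITIVITY_EXT,EVENT
77373,HCPCS,RAD,SENSITIVITY_EXT,EVENT
G0173,HCPCS,RAD,SENSITIVITY_EXT,EVENT
G0251,HCPCS,RAD,SENSITIVITY_EXT,EVENT
G0339,HCPCS,RAD,SENSITIVITY_EXT,EVENT
G0340,HCPCS,RAD,SENSITIVITY_EXT,EVENT
0082T,HCPCS,RAD,SENSITIVITY_EXT,EVENT
923*,ICD9_PX,RAD,SENSITIVITY_EXT,EVENT
785*,ICD9_PX,BS,SPECIFICITY,EVENT
790*,ICD9_PX,BS,SPECIFICITY,EVENT
791*,ICD9_PX,BS,SPECIFICITY,EVENT
793*,ICD9_PX,BS,SPECIFICITY,EVENT
8165,ICD9_PX,BS,SPECIFICITY,EVENT
8166,ICD9_PX,BS,SPECIFICITY,EVENT
22520,HCPCS,BS,SPECIFICITY,EVENT
22521,HCPCS,BS,SPECIFICITY,EVENT
22523,HCPCS,BS,SPECIFICITY,EVENT
22524,HCPCS,BS,SPECIFICITY,EVENT
22525,HCPCS,BS,SPECIFICITY,EVENT
27235,HCPCS,BS,SPECIFICITY,EVENT
27236,HCPCS,BS,SPECIFICITY,EVENT
27244,HCPCS,BS,SPECIFICITY,EVENT
27245,HCPCS,BS,SPECIFICITY,EVENT
E81*,ICD9_DX,NONE,SPECIFICITY,TRAUMA
E82*,ICD9_DX,NONE,SPECIFICITY,TRAUMA
E880*,ICD9_DX,NONE,SPECIFICITY,TRAUMA
E881*,ICD9_DX,NONE,SPECIFICITY,TRAUMA
E882*,ICD9_DX,NONE,SPECIFICITY,TRAUMA
E883*,ICD9_DX,NONE,SPECIFICITY,TRAUMA
E884*,ICD9_DX,NONE,SPECIFICITY,TRAUMA
E887*,ICD9_DX,NONE,SPECIFICITY,TRAUMA
E888*,ICD9_DX,NONE,SPECIFICITY,TRAUMA
E885*,ICD9_DX,NONE,SPECIFICITY,SAME_LEVEL_FALL
E886*,ICD9_DX,NONE,SPECIFICITY,SAME_LEVEL_FALL
1985,ICD9_DX,NONE,SPECIFICITY,RAD_CONTEXT
73390,ICD9_DX,NONE,SPECIFICITY,RAD_CONTEXT
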