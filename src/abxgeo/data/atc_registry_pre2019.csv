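atc_code,name,ddd_g_oral,ddd_g_parenteral,atc3,atc4_select,aware,default_route
J01AA02,doxycycline,0.1,0.1,J01A,,Access,oral
J01CA01,ampicillin,2,2,J01C,,Access,oral
J01CA04,amoxicillin,1,1,J01C,,Access,oral
J01CR02,amoxicillin-clavulanate,1,3,J01C,,Access,oral
J01DB04,cefazolin,,3,J01D,,Access,parenteral
J01DD04,ceftriaxone,,2,J01D,J01DD,Watch,parenteral
J01DH02,meropenem,,2,J01D,J01DH,Watch,parenteral
J01EE01,sulfamethoxazole-trimethoprim,1.92,1.92,J01E,,Access,oral
J01FA10,azithromycin,0.3,0.5,J01F,,Watch,oral
J01GB03,gentamicin,,0.24,J01G,,Access,parenteral
J01MA02,ciprofloxacin,1,0.5,J01M,,Watch,oral
J01XA01,vancomycin,2,2,J01X,,Watch,parenteral
J01XX08,linezolid,1.2,1.2,J01X,J01XX,Reserve,oral
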