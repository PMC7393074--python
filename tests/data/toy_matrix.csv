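run_id,p01,p02,p03,p04,p05,p06,p07,p08,p09,p10,p11,p12,p13,p14,p15,p16,p17,p18,p19,p20
A1,256,512,1024,2048,4096,8192,16384,32768,1024,2048,4096,,1024,,,1024,512,1024,4096,
A2,269,538,1075,2150,4301,8602,17203,34406,1075,2150,4301,,,,800,1075,538,1075,4301,
A3,512,1024,256,2048,1024,8192,32768,16384,2048,4096,,,,,,,512,1024,4096,1024
B1,300,600,1200,2400,4800,9600,19200,38400,1200,,,2400,,,768,1100,500,,4000,
B2,285,570,1140,2280,4560,9120,18240,36480,,,,2280,,2000,,,480,,3800,
B3,280,560,1100,2200,,,,,,,,,,,,,,,,
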