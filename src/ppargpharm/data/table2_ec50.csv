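complex,ligand,F1,F2,F3,F4,F5,F6,F7,ec50_low_nM,ec50_high_nM
1K74,544,+,+,+,+,+,+,+,0.2,2.7
1FM9,570,+,+,+,+,+,+,+,0.339,6
1FM6,BRL,+,+,+,+,+,-,-,2.4,2880
3AN4,M7R,-,+,+,+,+,-,-,3.6,3.6
3BC5,ZAA,+,-,+,+,+,+,-,4,4
3IA6,UNT,+,+,+,+,+,-,-,13,13
1I7I,AZ2,+,+,+,-,-,-,+,13,3528
3G9E,RO7,+,+,+,+,+,-,-,21,21
3AN3,M7S,-,+,+,+,+,-,-,22,22
2ZNO,S44,-,+,+,+,+,-,-,41,70
3GBK,2PQ,+,+,+,+,+,-,-,50,50
3VJI,J53,-,+,+,-,+,-,-,58,58
2F4B,EHA,+,-,+,-,+,-,-,70,70
2Q8S,L92,+,+,+,+,+,-,-,140,140
1KNU,YPA,+,+,+,+,+,-,+,170,170
3FEJ,CTM,+,+,+,-,+,-,+,210,210
2HWR,DRD,+,+,+,-,+,-,-,210,210
2ATH,3EA,+,+,+,-,+,-,-,230,230
2XKW,P1B,+,+,+,+,+,-,-,280,280
1NYX,DRF,+,+,+,-,+,-,-,570,600
2GTK,208,+,+,+,+,+,-,+,760,760
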