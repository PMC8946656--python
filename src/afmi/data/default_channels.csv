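index,ex_center_nm,ex_halfwidth_nm,em_low_nm,em_high_nm,fluorophore_hint
1,340.0,5.0,380.0,420.0,none
2,340.0,5.0,400.0,440.0,none
3,340.0,5.0,420.0,460.0,elastin
4,340.0,5.0,440.0,480.0,none
5,340.0,5.0,460.0,500.0,none
6,340.0,5.0,480.0,520.0,none
7,340.0,5.0,500.0,540.0,none
8,340.0,5.0,520.0,560.0,none
9,340.0,5.0,540.0,580.0,none
10,340.0,5.0,560.0,600.0,none
11,340.0,5.0,580.0,620.0,none
12,340.0,5.0,600.0,640.0,lipopigment
13,365.0,5.0,405.0,445.0,none
14,365.0,5.0,425.0,465.0,none
15,365.0,5.0,445.0,485.0,none
16,365.0,5.0,465.0,505.0,none
17,365.0,5.0,485.0,525.0,none
18,365.0,5.0,505.0,545.0,none
19,365.0,5.0,525.0,565.0,none
20,365.0,5.0,545.0,585.0,none
21,365.0,5.0,565.0,605.0,none
22,365.0,5.0,585.0,625.0,none
23,365.0,5.0,605.0,645.0,none
24,365.0,5.0,625.0,665.0,none
25,390.0,5.0,430.0,470.0,none
26,390.0,5.0,450.0,490.0,none
27,390.0,5.0,470.0,510.0,none
28,390.0,5.0,490.0,530.0,none
29,390.0,5.0,510.0,550.0,none
30,390.0,5.0,530.0,570.0,flavins
31,390.0,5.0,550.0,590.0,none
32,390.0,5.0,570.0,610.0,none
33,390.0,5.0,590.0,630.0,none
34,390.0,5.0,610.0,650.0,none
35,390.0,5.0,630.0,670.0,none
36,390.0,5.0,650.0,690.0,none
37,420.0,5.0,460.0,500.0,none
38,420.0,5.0,480.0,520.0,none
39,420.0,5.0,500.0,540.0,none
40,420.0,5.0,520.0,560.0,none
41,420.0,5.0,540.0,580.0,none
42,420.0,5.0,560.0,600.0,none
43,420.0,5.0,580.0,620.0,none
44,420.0,5.0,600.0,640.0,none
45,420.0,5.0,620.0,660.0,none
46,420.0,5.0,640.0,680.0,none
47,420.0,5.0,660.0,700.0,none
48,420.0,5.0,680.0,720.0,none
49,450.0,5.0,490.0,530.0,none
50,450.0,5.0,510.0,550.0,none
51,450.0,5.0,530.0,570.0,none
52,450.0,5.0,550.0,590.0,PPIX
53,450.0,5.0,570.0,610.0,none
54,450.0,5.0,590.0,630.0,none
55,450.0,5.0,610.0,650.0,none
56,450.0,5.0,630.0,670.0,none
57,450.0,5.0,650.0,690.0,none
58,450.0,5.0,670.0,710.0,none
59,450.0,5.0,690.0,730.0,none
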