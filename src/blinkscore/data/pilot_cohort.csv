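id,group,age,sex,electronics_use,regular_contact_lens,dry_gritty,eye_score,full_rate,partial_rate,duration,open_close_ratio_pct
1,CONTROL,58,M,+++,no,no,0,10,1,65,42.3
2,CONTROL,20,F,+++,yes,no,1,29,0,63,7.8
3,CONTROL,21,F,+++,no,no,0,25,5,61,9.1
4,CONTROL,22,F,+++,no,no,0,15,1,61,14.3
5,CONTROL,53,F,+,no,no,4,23,8,62,3.7
6,CONTROL,47,F,+++,yes,yes,6,21,6,62,2.4
7,CONTROL,56,F,+,yes,no,5,31,3,60,7.3
8,CONTROL,80,F,+,no,yes,3,22,1,60,4.0
9,CONTROL,65,M,+,no,yes,2,28,0,62,7.9
10,CONTROL,29,M,++++,no,no,0,18,0,58,18.4
DED1,DED,48,F,++++,yes,no,4,39,1,62,2.6
DED2,DED,80,M,++,no,yes,5,16,14,61,60
DED3,DED,83,F,+,no,yes,6,35,3,62,6.8
DED4,DED,21,F,+++,yes,no,7,36,8,61,3.4
DED5,DED,60,M,+++,yes,no,7,40,14,61,19.3
DED6,DED,51,F,+++,yes,yes,7,64,0,61,3.0
DED7,DED,28,F,++,yes,yes,6,13,6,61,9.9
DED8,DED,44,F,+,yes,,4,23,1,61,9.8
DED9,DED,60,M,++++,no,,6,55,0,61,3.9
DED10,DED,19,M,++++,yes,yes,9,53,11,61,7.2
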