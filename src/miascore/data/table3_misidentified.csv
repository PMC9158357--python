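patient_id,aneurysm_id,diameter_mm,location,shape,ruptured
1,1a,7.9,PcomA,irregular,no
1,1b,7.6,PcomA,irregular,yes
2,2a,5.3,PcomA,regular,no
2,2b,3.7,PcomA,regular,yes
3,3a,4.5,AcomA,irregular,no
3,3b,4.3,MCA,regular,no
3,3c,10.7,MCA,irregular,yes
4,4a,2.4,PcomA,irregular,no
4,4b,4.8,PcomA,regular,yes
5,5a,4.7,PcomA,irregular,no
5,5b,4.0,PcomA,regular,yes
6,6a,6.9,MCA,irregular,no
6,6b,4.1,MCA,regular,yes
7,7a,7.5,AA,regular,no
7,7b,6.1,AcomA,regular,yes
8,8a,6.1,MCA,irregular,no
8,8b,8.4,ICA,regular,yes
9,9a,7.3,MCA,irregular,no
9,9b,3.7,PcomA,regular,yes
10,10a,4.3,PcomA,regular,no
10,10b,5.3,ICA,regular,yes
11,11a,7.4,AcomA,irregular,no
11,11b,14,ICA,irregular,yes
12,12a,5.1,AcomA,regular,no
12,12b,3.6,MCA,regular,yes
13,13a,5.4,PcomA,regular,no
13,13b,11.6,MCA,regular,yes
14,14a,3.3,ICA,regular,no
14,14b,3,ICA,regular,yes
15,15a,6.8,MCA,irregular,no
15,15b,5.4,PcomA,irregular,no
15,15c,6.7,PcomA,regular,yes
16,16a,7,PcomA,irregular,no
16,16b,5.7,PcomA,irregular,yes
17,17a,2.8,MCA,regular,no
17,17b,7.1,PcomA,irregular,no
17,17c,3,ICA,regular,no
17,17d,6.6,PcomA,irregular,yes
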