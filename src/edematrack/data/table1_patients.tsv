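# Clinical summary of the 24 brain-tumor patients: peritumoral edema volume,
# lesion-to-tract distance (LTD) and motor-function decline (MRC <= 4).
# Transcription notes: case 19's edema volume is printed with a misplaced
# thousands separator ("1,7875 mm^3") and is stored as 17875.  The source
# text says six patients declined but its table marks seven "Yes" rows;
# the seven table labels are stored as printed.
case	edema_volume_mm3	ltd_mm	motor_decline
1	18658	37.2	0
2	8282	12.9	1
3	10648	17.4	0
4	24115	61.3	0
5	29935	40.6	0
6	27435	23.5	0
7	12283	16.4	0
8	26603	21.6	0
9	1870	11.3	0
10	17733	5.0	0
11	9557	10.0	0
12	33488	19.4	0
13	12180	3.8	0
14	24288	34.7	0
15	15738	4.8	1
16	6045	4.6	1
17	30948	36.5	0
18	5535	15.2	0
19	17875	16.4	1
20	7207	8.7	1
21	21523	40.2	0
22	8680	7.7	0
23	15620	2.3	1
24	19889	12.9	1
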