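# Reference fixture: 43 flavonoid peaks from the negative-mode UHPLC-Q-Exactive
# profile of Potentilla freyniana root extract (retention time in minutes,
# printed theoretical/experimental [M-H]- m/z, ppm error, neutral formula,
# MS2 fragments as "mz:relative_intensity", published identification).
# standard=1 marks peaks confirmed against an authentic reference standard.
# aglycone/conjugates/linkage restate the identification as the (skeleton,
# transformation multiset, glycosidic linkage) triple the annotator reports;
# "-" means not applicable.  Precursor intensities were not published; the
# loader substitutes a constant above the workflow's intensity floor.
peak	rt	mz_theor	mz_exp	error_ppm	formula	fragments	identification	standard	aglycone	conjugates	linkage
1	3.59	465.1038	465.1039	0.21	C21H22O12	285.0406:100;125.0233:72;275.0563:45;177.0185:29;303.0512:20;151.0032:17	Taxifolin-glucoside	0	taxifolin	glucoside	O
2	3.72	465.1038	465.1033	-1.08	C21H22O12	285.0405:100;125.0233:38;273.0043:28;177.0185:19;303.0511:15	Taxifolin-glucoside	0	taxifolin	glucoside	O
3	3.88	465.1038	465.1042	0.86	C21H22O12	285.0405:100;125.0233:36;177.0184:18;275.0566:12;303.0512:10	Taxifolin-glucoside	0	taxifolin	glucoside	O
4	4.13	463.0882	463.0881	-0.22	C21H20O12	287.0562:100;259.0612:78;125.0232:32	Eriodictyol-glucuronide	0	eriodictyol	glucuronide	O
5	4.19	449.1089	449.1093	0.89	C21H22O11	259.0611:100;287.0561:33;178.9979:15;125.0231:13	Eriodictyol-glucoside	0	eriodictyol	glucoside	O
6	4.41	593.1512	593.1535	3.88	C27H30O15	353.0667:100;383.0774:54;473.1092:35;125.0234:25;413.0874:6	Vicenin II	0	apigenin	glucoside+glucoside	C
7	4.56	449.1089	449.1092	0.67	C21H22O11	259.0612:100;269.0455:76;287.0563:44;125.0233:38;178.9977:22	Eriodictyol-glucoside	0	eriodictyol	glucoside	O
8	5.61	465.1038	465.1042	0.86	C21H22O12	125.0233:100;285.0405:62;259.0610:48;275.0566:32;303.0512:18	Taxifolin-glucoside	0	taxifolin	glucoside	O
9	5.75	479.0831	479.0834	0.63	C21H20O13	285.0405:100;125.0233:41;303.0512:18;177.0186:17;169.0133:15;259.0613:14	Taxifolin-glucuronide	0	taxifolin	glucuronide	O
10	5.88	449.1089	449.1092	0.67	C21H22O11	269.0456:100;151.0026:69;178.9979:39;125.0231:13;259.0612:12;287.0562:10	Eriodictyol-glucoside	0	eriodictyol	glucoside	O
11	6.12	433.1140	433.1142	0.46	C21H22O10	271.0614:100;151.0027:73;119.0491:18;125.0229:8	Naringenin-glucoside	0	naringenin	glucoside	O
12	6.22	625.1408	625.1408	0.00	C27H30O17	287.0558:100;113.0231:40;151.0030:38	Eriodictyol-glucoside-glucuronide	0	eriodictyol	glucuronide+glucoside	O
13	6.57	303.0510	303.0507	-0.99	C15H12O7	125.0234:100;285.0407:38	Taxifolin	0	taxifolin	-	-
14	6.59	433.1140	433.1141	0.23	C21H22O10	271.0613:100;151.0027:72;119.0491:16	Naringenin-glucoside	0	naringenin	glucoside	O
15	6.85	463.0882	463.0886	0.86	C21H20O12	300.0272:100;301.0350:70	Hyperoside	1	quercetin	glucoside	O
16	6.90	449.1089	449.1094	1.11	C21H22O11	151.0028:100;287.0562:73;135.0442:32	Eriodictyol-glucoside	0	eriodictyol	glucoside	O
17	7.18	463.0882	463.0886	0.86	C21H20O12	300.0279:100;301.0358:50;151.0025:8;178.9976:7	Isoquercitrin	1	quercetin	glucoside	O
18	7.75	597.1825	597.1832	1.17	C27H34O15	357.0983:100;387.1087:85;315.0882:22;417.1165:21;358.1008:15	Phloretin-C-diglucoside	0	phloretin	glucoside+glucoside	C
19	7.99	449.1089	449.1085	-0.89	C21H22O11	167.0340:69;137.0233:50;123.0441:12	Phloretin-glucuronide	0	phloretin	glucuronide	undetermined
20	8.15	431.0984	431.0992	1.86	C21H20O10	269.0445:100	Baicalein-glucoside	0	baicalein	glucoside	O
21	9.60	431.0984	431.0988	0.93	C21H20O10	269.0443:100	Baicalein-glucoside	0	baicalein	glucoside	O
22	9.61	449.1089	449.1086	-0.67	C21H22O11	151.0026:100;287.0563:65;135.0442:22	Eriodictyol-glucoside	0	eriodictyol	glucoside	O
23	9.68	565.1563	565.1568	0.88	C26H30O14	271.0614:100;151.0026:48	Naringenin-pentoside-glucoside	0	naringenin	glucoside+pentoside	O
24	9.82	433.1140	433.1142	0.46	C21H22O10	271.0615:100;151.0028:41;119.0491:14	Naringenin-glucoside	0	naringenin	glucoside	O
25	10.38	431.0984	431.0992	1.86	C21H20O10	268.0369:100;269.0444:47	Apigenin-7-glucoside	0	apigenin	glucoside	O
26	11.18	463.0882	463.0886	0.86	C21H20O12	151.0027:100;113.0231:66;287.0562:52;161.0234:40;337.0569:39;135.0439:23	Eriodictyol-glucuronide	0	eriodictyol	glucuronide	O
27	12.16	435.1297	435.1300	0.69	C21H24O10	273.0769:100;167.0340:69;125.0023:9;179.0341:6	Phlorizin	1	phloretin	glucoside	O
28	12.36	477.0674	477.0678	0.84	C21H18O13	301.0353:100;151.0029:11;178.9983:9	Quercetin-glucuronide	0	quercetin	glucuronide	O
29	12.51	431.0984	431.0986	0.46	C21H20O10	268.0371:100;269.0441:18;239.0337:9	Apigenin-4'-glucoside	0	apigenin	glucoside	O
30	12.62	477.0674	477.0678	0.84	C21H18O13	301.0354:100;178.9983:12;151.0029:8	Quercetin-glucuronide	0	quercetin	glucuronide	O
31	13.00	433.1140	433.1144	0.92	C21H22O10	271.0612:100;151.0027:46	Naringenin-glucoside	0	naringenin	glucoside	O
32	13.39	567.1719	567.1730	1.94	C26H32O14	273.0771:100;167.0340:42;125.0020:22	Phloretin-pentoside-glucoside	0	phloretin	glucoside+pentoside	O
33	13.45	287.0561	287.0564	1.05	C15H12O6	151.0027:100;135.0441:69;107.0125:10	Eriodictyol	1	eriodictyol	-	-
34	13.57	449.1089	449.1085	-0.89	C21H22O11	137.0233:100;167.0340:89;123.0440:8	Phloretin-glucuronide	0	phloretin	glucuronide	undetermined
35	13.67	435.1297	435.1303	1.38	C21H24O10	273.0767:100;167.0339:52	Trilobatin	1	phloretin	glucoside	O
36	13.86	301.0354	301.0356	0.66	C15H10O7	151.0027:100;178.9978:66;121.0284:21;107.0125:8	Quercetin	1	quercetin	-	-
37	13.95	285.0405	285.0407	0.70	C15H10O6	285.0404:100;151.0033:12;133.0290:11;175.0395:8	Luteolin	1	luteolin	-	-
38	14.79	271.0611	271.0614	1.11	C15H12O5	151.0027:100;119.0499:36;177.0184:14;93.0333:14;107.0126:9	Naringenin	1	naringenin	-	-
39	14.95	269.0455	269.0454	-0.37	C15H10O5	269.0455:100;117.0344:8;149.0239:7;151.0035:7	Apigenin	1	apigenin	-	-
40	14.99	273.0768	273.0771	1.10	C15H14O5	167.0341:100;123.0438:18;119.0491:12;125.0231:8	Phloretin	1	phloretin	-	-
41	15.07	285.0405	285.0405	0.00	C15H10O6	285.0403:100;151.0030:5	Kaempferol	1	kaempferol	-	-
42	15.49	269.0455	269.0453	-0.74	C15H10O5	269.0453:100;241.0504:9;251.0348:8;223.0399:7	Baicalein	1	baicalein	-	-
43	16.71	283.0612	283.0613	0.35	C16H12O5	268.0376:100;163.0035:7	Wogonin	1	wogonin	-	-
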