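sample	ngs_cnv	karyotype	interpretation
1	5q-, 7q-, 18p-, 19p+, 19q+, 21q+(amplification)	46 48,XX,-5,r(7),-18,add(19)(p13.1),der(21)t(5;21)(q13;p11.2),+2 5mar[cp16]/46,XX[4]	complex (Yes)
2	5q-, 7q-, -18 (bi-allelic 18p-), 19p+, 19q+, 21q+(amplification)	46 48,XX,-5,r(7),-18,add(19)(p13.1),der(21)t(5;21)(q13;p11.2),+2 5mar[cp16]/46,XX[4]	complex (Yes)
3	1q+, 7q-, 19q+, 21q+	46,XY,+1,der(1;7)(q10;p10)[2]/47,idem,+21[14]/48,idem,+8,+21[2]/47,idem,+8[1]/46,XY[1]	complex (Yes)
4	5q-, 8q+, and 17p-	46,XX,del(3)(q21q25),add(5)(p13),del(5)(q13q33),-17,der(17;21)(q10;q10),add(21)(p11.2),+mar[cp20]	poor (Yes)
5	5q-, 7q-, +8, 17p-, 17q1(proximal), 17q+(distal),-19, +21	46 47,XY,del(5)(q15q34),add(7)(q21),+8,del(11)(q22q23),-17,-19, -22,+2 3mar[15]/46,XY[5]	poor (Yes)
6	5q-; 7q-, 17p-, 18q-	45,XX,del(5)(q13q33),-7,der(17)add(17)(p11.1)add(17)(q23),del(18)(q21.3q23)[12]/45,XX,del(5)(q13q33),dic(7;17)(q11.2;p11.1),del(18)(q21.3q23)[3]/46,XX[5]	complex (Yes)
7	2p-, 3p-, 5q-, 17p-, 17q-(partial), 19p+, 21q+	42 43,XY,add(3)(p13),-2,-3,-5,add(16)(q12.1),-17,add(19)(q13.1),-20,+2mar,inc[cp3] LIMITED STUDY	complex (Yes)
8	3p-, 5q-, 7q-, 12p- and +22.	45,X,-Y,add(1)(q21),del(3)(p13p25),dic(5;12)(q11.2;p11.2),add(7)(q11.2),+mar[19]/46,XY[1]	complex (Yes)
9	monosomy 7	45, XX,-7[9]/46.xx[11]	poor (Yes)
10	5q-, +8, +11, +13, and 17q-	40 48,XY,+5,del(5)(q15q33),der(5;14)(p10;q10),der(5;17)(p10;q10),-7,+8,i(11)(q10),idic(13)(p11.2),add(14)(p11.2),add(16)(q24),i(17)(q10),-18,der(20)t(11;20)(q13;q13.3),-21,+22,+mar[cp17]/46,XY[3]	complex (Yes)
11	5q-, -7, 11q+, 12p-, 17p-, 18p-, 19q+	44,XY,-5,-7,inv(12)(p13q13),add(17)(p11.2),-18,der(19)ins(19);?(q13.1);?,-20,+2mar[8]/43,idem,-11,add(13)(q32)[5]/44,idem,r(11)(p15q25)[2]/46,XY[7]	complex (Yes)
12	-5, 8p+, 9p-,11p-, 17p-, -18 and 20p-	45,XX,add(3)(q21),add(5) (q11.2)x2, der(6)t(6;17) (q27;q11.2),add(7) (q31),+8,der(13)t(5;13) (q15;q32),-17,1-18[10]/46,XX[4] INCOMPLETE STUDY	complex (Yes)
13	5q-, 8q+, 11p+(proximal amplification), 11q (KMT2A gene amplification), +13.	48,XY,del(5)(q13q33),+8,+mar[20]	poor (Yes)
14	3p-, 5q-, -7, and 12p-	43 44,XX,-3,dic(5;15)(q11.2;p11.2),-6,del(6)(p23p25),der(7;12)t(7;12)(p10;q10)ins(7);?(p11.2);?,+der()?t(?;3)(?;q12),+r[cp17]/46,XX[3]	complex (Yes)
15	4q-, 5q-, 7q-, +11, 12p-, 13p+, 13q+, -16, 17p-, -18, +21 and +Y.	44 50,XYY?c,-4,dic(5;17)(q13;p11.2),add(7)(q11.2),der(12)ins(12);?(q13);?,-14,-21,-22,+2 8mar[cp14]/47 48,idem,+11,+13[cp3]/81 89,idemx2[2]/47,XYY?c[8]	complex (Yes)
16	7q-	46, XX, del(7)(q22q32)[19]/46,XX[1]	poor (Yes)
17	12p-	46,XY[20]	intermediate (Yes)
18	1q+, 2p+, 3q-, -4, -7, 9q+, 13q+, 17p-, 17q-, 20q+, 21q-	44 46,XY,add(2)(p11.2),-3,add(3)(q11.2),add(4)(q12),-5,der(5)t(3;5)(p13;p13)ins(5);?(p13);?,del(6)(p23p25),-9,add(13)(q12),-17,-17,add(20)(q11.2),+3 5mar,inc[cp5] Limited Study	complex (Yes)
19	1q+ and trisomy 14.	46,XY,i(14)(q10)[20]	intermediate (Yes)
20	8p-, 9p- (PAX5, CD174, CDKN2A/B), 17p- and gain:1p+, 17p+.	45,XY,der(8)t(1;8)(q12;p21),inv(8)(p11.2q24.3),add(9)(p13),i(17)(q10),-20[4]/46,XY[20]	poor (Yes)
21	1p-, 5q-, -7, 10p-, 12p-, 17q-, 18q- and 20q-	43 45,XX,der(1)del(1)(p12p31)add(1)(q12),+3,add(3)(p11.2),add(3)(q11.2), del(5)(q13q34),add(6)(q21),-7,-10,del(10)(p13p15), der(11)t(11;17)(q23;q11.2),-12,-16,-17,add(17)(q11.2),add(18)(q21.1),add(18)(q21.3),-20,del(21)(q21q22),+3 4mar[cp13]/89 90,slx2[2]/46,XX[5]	complex (Yes)
22	3q-, 5q-, 7p-, 8q+, 12p-, 12q-, -16, 17p-, -18, -20	43,XY,del(5)(q13q33),del(7)(p13p22),add(9)(q13),der(12)add(12)(p11.2)del(12)(q14q21),-16,-18,-20[20]	complex (Yes)
23	+8 and 10q-	46,XY,der(4)t(4;8)(q33;q13),t(8;21)(q22;q22)[7]/47,XY,+8,t(8;21)(q22;q22)[5], LIMITED ANALYSIS	intermediate (Yes)
24	3p-, 5q-, -7, +8, 16q-, 17p-, 18q-, +21	44,XX,-3,del(5)(q15q34),r(7),+8,-16,add(17)(p11.2),-18,add(21)(q22)[20]	complex (Yes)
25	Trisomy 21	47,XX,+21[13]/46,XX[3]	intermediate (Yes)
26	8p+, 18p-	47,XY,+8[4]/46,XY[16]	intermediate (Yes)
27	1q+, 8q+	47,XY,dup(1)(q11q44),+8[17]/46,XY[3]	intermediate (Yes)
28	1p+, 5q-, +6, 7q-, -11, 17p- and others	44,XY,add(2)(p11.2),der(5)t(5;17)(q15;q21),add(6)(p21.3),del(7)(q22q36),-11,del(13)(q12q14),-14,der(16)t(14;16)(q24;q11.2),-17,add(21)(q22),+r[19]/46,XY[1]	complex (Yes)
29	monosomy 7 and 12p-	46,XY,r(7)[3]/46,XY[1], LIMITED ANALYSIS	poor (Yes)
30	Normal	92,XXXX,add(12)(q24.1)x2[20]	intermediate (Yes)
31	9p-	46,XY,del(9)(q13q34)[3]/46,XY[17]	intermediate (Yes)
32	2q+, 2q-(distal, IDH1 and ERBB4 deletion), 3p-, 5q-, 7q-, and 12p-.	39 45,XX,add(2)(q22),del(3)(p11),dic(5;7)(q11.2;q11.1),-12,-17,+mar[cp19]/46,XX[1]	complex (Yes)
33	5q+ (gain)	46,XX[20]	intermediate (Yes)
34	9p-(deletion of CDKN2A and CDKN2B)	NO METAPHASES DETECTED	poor (N/A)
35	7q- and 8q+	NO METAPHASES DETECTED	poor (N/A)
36	12p-	NO METAPHASES DETECTED	intermediate (N/A)
37	normal	No Metaphases Detected	intermediate (N/A)
38	Normal	NO METAPHASES DETECTED	intermediate (N/A)
39	Normal	NO METAPHASES DETECTED	intermediate (N/A)
40	Normal	No Metaphases Detected	intermediate (N/A)
41	Normal	NO METAPHASES DETECTED	intermediate (N/A)
42	Normal	46,XX,t(9;22)(q34;q11.2)[4]/46,XX[16]	no loss/gain (Yes)
43	Normal	46,XX,inv(16)(p13.1q22)[22]	no loss/gain (Yes)
44	Normal	46,XY,t(9;22)(q34;q11.2)[20]	no loss/gain (Yes)
	45 sample with no chromosomal abnormalities	45 samples with Normal Karyotype	45 sample (Yes)
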