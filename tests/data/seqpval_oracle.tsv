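z1	z_pooled	w1	gamma1	p_mc	p_quad	mc_se
-2.833412234	1	0.25	0.01	0.0069933	0.006965366252	2.635221766e-05
-2.833412234	2	0.25	0.01	0.0026337	0.002638319442	1.620729349e-05
-2.833412234	3	0.25	0.01	0.000379	0.0003864070556	6.15513086e-06
-2.833412234	1	0.3333333333	0.01	0.0078235	0.007895857799	2.786089167e-05
-2.833412234	2	0.3333333333	0.01	0.0034339	0.003452164691	1.84989414e-05
-2.833412234	3	0.3333333333	0.01	0.0005455	0.0005565812036	7.38378243e-06
-2.833412234	1	0.5	0.01	0.0092616	0.009229431683	3.029162057e-05
-2.833412234	2	0.5	0.01	0.0052418	0.005220905581	2.283489333e-05
-2.833412234	3	0.5	0.01	0.0009866	0.0009782526328	9.927872987e-06
-1.80933899	1	0.25	0.1	0.0523894	0.05239135764	7.045903119e-05
-1.80933899	2	0.25	0.1	0.0137388	0.01373507536	3.681038627e-05
-1.80933899	3	0.25	0.1	0.001339	0.001345034003	1.156376703e-05
-1.80933899	1	0.3333333333	0.1	0.0593233	0.05925845318	7.470210578e-05
-1.80933899	2	0.3333333333	0.1	0.0168626	0.01686839668	4.071640053e-05
-1.80933899	3	0.3333333333	0.1	0.0016791	0.001668557636	1.294712564e-05
-1.80933899	1	0.5	0.1	0.0727812	0.07274318264	8.214870475e-05
-1.80933899	2	0.5	0.1	0.0234144	0.02341667539	4.781857994e-05
-1.80933899	3	0.5	0.1	0.0022407	0.002220846335	1.495218801e-05
-0.7419387252	1	0.25	0.5	0.1876046	0.1876495535	0.0001234540862
-0.7419387252	2	0.25	0.5	0.0334535	0.03349176214	5.686331272e-05
-0.7419387252	3	0.25	0.5	0.0023312	0.002346854437	1.525046067e-05
-0.7419387252	1	0.3333333333	0.5	0.1987026	0.1988794638	0.0001261823588
-0.7419387252	2	0.3333333333	0.5	0.0366132	0.03655552393	5.939080197e-05
-0.7419387252	3	0.3333333333	0.5	0.0025296	0.002511964409	1.588458726e-05
-0.7419387252	1	0.5	0.5	0.2241111	0.2241877418	0.0001318655811
-0.7419387252	2	0.5	0.5	0.0415021	0.04152460378	6.307113103e-05
-0.7419387252	3	0.5	0.5	0.0026556	0.002668324767	1.627435955e-05
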