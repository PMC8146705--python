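marker,T,TE-50/50,TP-50/50,TP-60/40,TP-70/30,TA-50/50,TA-60/40,TA-70/30
Alfalfa 1,79,88,72,54,58,65,92,100
Alfalfa 2,14,35,41,52,45,67,100,75
Alfalfa 3,3,57,59,58,41,100,98,42
Broad bean 1,30,90,72,76,49,72,100,88
Broad bean 2,26,76,63,72,51,74,100,96
Broad bean 3,94,76,48,55,56,90,100,92
Chickpea 1,47,36,62,71,65,87,98,100
Chickpea 2,16,22,72,72,38,87,100,82
Chickpea 3,27,23,60,47,27,100,100,77
Lentil 1,12,20,76,74,39,87,100,79
Lentil 2,10,18,63,65,36,87,100,80
Lentil 3,7,14,36,67,36,83,100,78
Lupine blue 1,38,42,74,84,77,100,98,98
Lupine blue 2,19,17,45,54,40,92,100,89
Lupine blue 3,15,6,37,48,36,82,100,90
Lupine white 1,38,42,74,84,77,100,98,98
Lupine white 2,19,17,45,54,40,92,100,89
Lupine white 3,15,11,37,48,35,82,100,90
Pea 1,21,35,85,84,72,83,100,85
Pea 2,28,24,66,73,68,85,100,89
Pea 3,22,21,54,62,58,86,100,85
Peanut 1,69,43,71,70,61,98,100,87
Peanut 2,70,24,57,49,39,100,91,60
Peanut 3,73,59,81,71,72,100,82,59
Soy 1,29,29,67,67,58,96,100,93
Soy 2,6,16,52,43,27,100,98,68
Soy 3,28,33,77,60,53,95,100,86
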