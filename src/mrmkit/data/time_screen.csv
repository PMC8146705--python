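marker,30,60,90,120,150,180
Alfalfa 1,69,86,97,42,100,44
Alfalfa 2,93,89,66,92,91,100
Alfalfa 3,100,90,39,97,97,84
Broad bean 1,100,96,83,94,96,98
Broad bean 2,100,96,84,87,85,92
Broad bean 3,93,96,97,93,96,100
Chickpea 1,91,88,88,100,95,92
Chickpea 2,100,86,88,89,97,81
Chickpea 3,97,88,88,89,100,95
Lentil 1,79,88,90,94,100,96
Lentil 2,83,90,89,96,100,98
Lentil 3,92,89,92,100,100,98
Lupine blue 1,100,90,75,83,87,86
Lupine blue 2,100,100,70,83,81,80
Lupine blue 3,100,88,54,96,96,100
Lupine white 1,99,95,95,100,94,89
Lupine white 2,89,95,97,98,100,95
Lupine white 3,80,88,90,95,100,96
Pea 1,89,100,100,93,80,95
Pea 2,94,100,100,90,94,91
Pea 3,99,100,94,93,95,95
Peanut 1,100,86,81,71,61,56
Peanut 2,100,90,94,82,91,92
Peanut 3,100,83,85,72,79,80
Soy 1,100,80,77,77,73,68
Soy 2,100,95,87,94,88,77
Soy 3,100,92,89,92,86,75
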