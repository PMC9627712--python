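year	season	count
1972	spring	224
1972	autumn	473
1976	spring	218
1976	autumn	509
1980	spring	187
1980	autumn	442
1984	spring	205
1984	autumn	395
1988	spring	163
1988	autumn	411
1992	spring	196
1992	autumn	320
1996	spring	229
1996	autumn	361
2000	spring	171
2000	autumn	288
2004	spring	96
2004	autumn	214
2006	spring	61
2006	autumn	126
2008	spring	47
2008	autumn	119
2010	spring	66
2010	autumn	112
2013	spring	35
2013	autumn	92
2016	spring	115
2016	autumn	144
2019	spring	136
2019	autumn	170
2021	spring	175
2021	autumn	263
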