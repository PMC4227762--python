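chrom	pos	global_p
1	228757936	0
2	133018988	0.248
2	133020085	0.0005
2	207122438	0
2	69347244	0.582
2	133033524	0.2535
2	133029769	0.4335
2	133032580	0
3	162561619	0
4	7635629	0
4	89618837	0
4	49099668	0
5	178650557	0
6	170055316	0
6	3849305	0
6	168784228	0
7	64895556	0.0265
7	157923845	0.3995
7	61080848	1
7	56437045	0
7	19534519	0.307
7	57554497	0.0205
10	42800026	0.5405
11	2721568	0
11	51579458	0.5285
13	31481030	0.096
14	88237822	0.17
15	25123472	0
15	25201659	0
16	46411729	0
16	3493495	0
16	11415785	0.002
17	22252007	0.74
17	22259640	0.7215
18	18517029	0
19	15279411	0
19	57350463	0
19	24184564	0
20	57415110	0
20	57431165	0.0625
21	44011806	0.0145
21	40757887	0
22	42078666	0
22	49077801	0.715
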