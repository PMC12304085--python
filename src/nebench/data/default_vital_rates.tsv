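# nebench vital-rates config
max_age	15
maturity_age	4
sex_ratio	0.5
provenance	reconstructed
# age	survival	fertility
0	1.0	0.0
1	0.6164367197340965	0.0
2	0.6099573027781251	0.0
3	0.6034067160382257	0.0
4	0.596785722644069	4.956969719174246
5	0.5900951610426322	5.956969719174246
6	0.5833359470229953	6.956969719174246
7	0.576509075707609	7.956969719174246
8	0.5696156235032599	8.956969719174246
9	0.5626567500046145	9.956969719174246
10	0.5556336998428557	10.956969719174246
11	0.5485478044715716	11.956969719174246
12	0.5414004838816983	12.956969719174246
13	0.5341932482369666	13.956969719174246
14	0.5269276994209533	14.956969719174246
15	0.0	15.956969719174246
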