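statistic	1	2	5	10	20	30	40	50
mean_tpr	100	100	100	100	76.5	70.5	68.0	53.6
mean_tnr	0	0	0.2	4.0	66.2	78.3	88.1	94.1
median_tpr	100	100	100	100	80	74.6	70.7	55
median_tnr	0	0	0.1	3.2	63.7	78.8	90.4	96.6
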