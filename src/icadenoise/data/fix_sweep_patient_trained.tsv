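statistic	1	2	5	10	20	30	40	50
mean_tpr	98.1	97.7	97.3	96.3	91.7	88	83.6	79.4
mean_tnr	61.3	65.3	71.8	78.5	86.9	91.6	94	96
median_tpr	100	100	100	100	100	100	88.9	87.5
median_tnr	62.2	66.7	73.6	79.2	88.1	92.3	94.4	96.2
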