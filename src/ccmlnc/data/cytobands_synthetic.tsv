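chr7	0	4000000	p22.3	gneg
chr7	4000000	7000000	p22.2	gneg
chr7	7000000	11000000	p22.1	gneg
chr7	11000000	16000000	p21.3	gneg
chr7	16000000	19000000	p21.2	gneg
chr7	19000000	25000000	p21.1	gneg
chr7	25000000	28000000	p15.3	gneg
chr7	28000000	30000000	p15.2	gneg
chr7	30000000	34000000	p15.1	gneg
chr7	34000000	38000000	p14.3	gneg
chr7	38000000	41000000	p14.2	gneg
chr7	41000000	46000000	p14.1	gneg
chr7	46000000	51000000	p13	gneg
chr7	51000000	54000000	p12.3	gneg
chr7	54000000	57000000	p12.2	gneg
chr7	57000000	61000000	p12.1	gneg
chr7	61000000	65000000	p11.2	gneg
chr7	65000000	67000000	p11.1	gneg
chr7	67000000	69000000	q11.1	gneg
chr7	69000000	74000000	q11.21	gneg
chr7	74000000	77000000	q11.22	gneg
chr7	77000000	82000000	q11.23	gneg
chr7	82000000	87000000	q21.11	gneg
chr7	87000000	90000000	q21.12	gneg
chr7	90000000	94000000	q21.13	gneg
chr7	94000000	98000000	q21.2	gneg
chr7	98000000	104000000	q21.3	gneg
chr7	104000000	108000000	q22.1	gneg
chr7	108000000	111000000	q22.2	gneg
chr7	111000000	116000000	q22.3	gneg
chr7	116000000	121000000	q31.1	gneg
chr7	121000000	125000000	q31.2	gneg
chr7	125000000	128000000	q31.31	gneg
chr7	128000000	131000000	q31.32	gneg
chr7	131000000	135000000	q31.33	gneg
chr7	135000000	140000000	q32.1	gneg
chr7	140000000	144000000	q32.2	gneg
chr7	144000000	148000000	q32.3	gneg
chr7	148000000	153000000	q33	gneg
chr7	153000000	157000000	q34	gneg
chr7	157000000	162000000	q35	gneg
chr7	162000000	166000000	q36.1	gneg
chr7	166000000	169000000	q36.2	gneg
chr7	169000000	173000000	q36.3	gneg
chr3	0	3000000	p26.3	gneg
chr3	3000000	6000000	p26.2	gneg
chr3	6000000	10000000	p26.1	gneg
chr3	10000000	14000000	p25.3	gneg
chr3	14000000	17000000	p25.2	gneg
chr3	17000000	21000000	p25.1	gneg
chr3	21000000	25000000	p24.3	gneg
chr3	25000000	28000000	p24.2	gneg
chr3	28000000	32000000	p24.1	gneg
chr3	32000000	36000000	p23	gneg
chr3	36000000	40000000	p22.3	gneg
chr3	40000000	43000000	p22.2	gneg
chr3	43000000	47000000	p22.1	gneg
chr3	47000000	50000000	p21.33	gneg
chr3	50000000	52000000	p21.32	gneg
chr3	52000000	56000000	p21.31	gneg
chr3	56000000	60000000	p21.2	gneg
chr3	60000000	65000000	p21.1	gneg
chr3	65000000	69000000	p14.3	gneg
chr3	69000000	72000000	p14.2	gneg
chr3	72000000	76000000	p14.1	gneg
chr3	76000000	80000000	p13	gneg
chr3	80000000	83000000	p12.3	gneg
chr3	83000000	86000000	p12.2	gneg
chr3	86000000	89000000	p12.1	gneg
chr3	89000000	92000000	p11.2	gneg
chr3	92000000	94000000	p11.1	gneg
chr3	94000000	96000000	q11.1	gneg
chr3	96000000	100000000	q11.2	gneg
chr3	100000000	104000000	q12.1	gneg
chr3	104000000	107000000	q12.2	gneg
chr3	107000000	110000000	q12.3	gneg
chr3	110000000	113000000	q13.11	gneg
chr3	113000000	115000000	q13.12	gneg
chr3	115000000	118000000	q13.13	gneg
chr3	118000000	122000000	q13.2	gneg
chr3	122000000	126000000	q13.31	gneg
chr3	126000000	129000000	q13.32	gneg
chr3	129000000	133000000	q13.33	gneg
chr3	133000000	137000000	q21.1	gneg
chr3	137000000	140000000	q21.2	gneg
chr3	140000000	144000000	q21.3	gneg
chr3	144000000	147000000	q22.1	gneg
chr3	147000000	150000000	q22.2	gneg
chr3	150000000	154000000	q22.3	gneg
chr3	154000000	158000000	q23	gneg
chr3	158000000	163000000	q24	gneg
chr3	163000000	166000000	q25.1	gneg
chr3	166000000	169000000	q25.2	gneg
chr3	169000000	172000000	q25.31	gneg
chr3	172000000	174000000	q25.32	gneg
chr3	174000000	177000000	q25.33	gneg
chr3	177000000	180000000	q26.1	gneg
chr3	180000000	183000000	q26.2	gneg
chr3	183000000	186000000	q26.31	gneg
chr3	186000000	189000000	q26.32	gneg
chr3	189000000	193000000	q26.33	gneg
chr3	193000000	196000000	q27.1	gneg
chr3	196000000	199000000	q27.2	gneg
chr3	199000000	202000000	q27.3	gneg
chr3	202000000	206000000	q28	gneg
chr3	206000000	211000000	q29	gneg
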