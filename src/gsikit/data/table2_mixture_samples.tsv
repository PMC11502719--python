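ecoregion	source	year	n
North Sea	HERAS	2019	672
North Sea	HERAS	2020	825
North Sea	HERAS	2021	785
North Sea	HERAS	2022	1188
North Sea	HERAS	2023	1247
North Sea	Commercial	2021	1232
North Sea	Commercial	2022	1947
North Sea	Commercial	2023	3453
Norwegian Sea	IESNS	2020	188
Norwegian Sea	IESNS	2021	273
Norwegian Sea	IESNS	2022	235
Norwegian Sea	IESSNS	2019	286
Norwegian Sea	IESSNS	2020	599
Norwegian Sea	IESSNS	2021	1174
Norwegian Sea	IESSNS	2022	1566
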