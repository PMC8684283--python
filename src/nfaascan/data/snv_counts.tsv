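breed	subspecies	ars_ucd12_snvs	uoa_brahman1_snvs
Angus	taurus	11396537	17143672
Hereford	taurus	9971428	16734834
Holstein	taurus	11133911	11459171
Jersey	taurus	9512074	15423670
Shorthorn	taurus	8464487	14393682
Simmental	taurus	14988534	20404489
Bohai	indicus	16102113	19819636
Boran	indicus	27861344	27757944
Brahman	indicus	33177201	30592708
Gir	indicus	24288498	22426843
Indianzebu	indicus	20210906	18518614
Kenana	indicus	26760622	24953316
Mangshi	indicus	21993501	20859379
Nelore	indicus	22770177	21279805
Ogaden	indicus	25330919	24224387
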