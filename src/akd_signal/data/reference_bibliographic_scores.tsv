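ingredient	atc_class	n_reports	phenotype	ic025	ror	score
Esomeprazole	A	9198	Renal injury	6.8	184.23	4
Pantoprazole	A	3403	Tubulointerstitial nephritis	6.3	109.86	4
Tenofovir disoproxil	J	6461	Renal failure	6.0	90.72	4
Efavirenz + emtricitabine + tenofovir disoproxil	J	4359	Renal failure	5.9	76.08	4
Colistin	J	956	Blood creatinine increased	5.7	66.70	4
Furosemide	C	5935	Acute kidney injury	3.9	17.72	4
Tacrolimus	L	2115	Blood creatinine increased	3.6	13.12	4
Omeprazole	A	456	Tubulointerstitial nephritis	6.0	6.91	4
Ibuprofen	M	625	Tubulointerstitial nephritis	2.6	6.76	4
Emtricitabine + tenofovir disoproxil	J	7781	Renal injury	7.9	432.36	3
Sodium phosphate	A	728	Acute kidney injury	5.4	57.80	3
Basiliximab	L	85	Tubulointerstitial nephritis	4.7	41.53	3
Spironolactone	C	2644	Acute kidney injury	4.3	22.28	3
Vancomycin	J	3395	Blood creatinine increased	5.8	20.73	3
Canagliflozin	A	1801	Acute kidney injury	4.0	18.48	3
Acyclovir	J	2097	Acute kidney injury	3.6	13.68	3
Lenalidomide	L	3507	Renal failure	1.7	3.50	3
Methotrexate	L	2654	Acute kidney injury	1.5	2.93	3
Inotersen	N	182	Glomerular filtration rate decreased	7.7	604.57	2
Ciclosporine	L	1495	Blood creatinine increased	3.4	11.86	2
Rivaroxaban	L	3425	Acute kidney injury	2.1	4.64	2
Cobicistat + elvitegravir + emtricitabine + tenofovir disoproxil	J	3105	Renal injury	8.7	786.96	1
Metformine	A	5232	Acute kidney injury	3.5	9.92	0
COVID-19 vaccine	J	5407	Acute kidney injury	-2.0	0.24	0
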