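# Default acute-kidney-disease case definition: MedDRA-like preferred terms.
# One term per line; matching is case- and whitespace-insensitive.
acute kidney injury
renal failure
renal impairment
blood creatinine increased
renal injury
blood urea increased
tubulointerstitial nephritis
glomerular filtration rate decreased
oliguria
anuria
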