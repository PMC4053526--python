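# KIR3DL1/KIR3DS1 allelic frequencies from sequence-based typing of a
# cohort of healthy donors (two alleles per diploid donor).
# The *001/*016 row is printed jointly in the source and kept as one entry
# covering two alleles.
# donors: 426
allele	frequency_pct	n_alleles
KIR3DS1*013	19.80	1
KIR3DL1*001/*016	18.80	2
KIR3DL1*004	15.80	1
KIR3DL1*005	14.00	1
KIR3DL1*002	11.50	1
KIR3DL1*015	6.20	1
KIR3DL1*008	5.50	1
KIR3DL1*007	2.70	1
KIR3DL1*009	1.90	1
KIR3DL1*020	1.30	1
KIR3DL1*019	0.94	1
KIR3DL1*049	0.47	1
KIR3DL1*052	0.35	1
KIR3DL1*014	0.12	1
KIR3DL1*018	0.12	1
KIR3DL1*030	0.12	1
KIR3DL1*053	0.12	1
KIR3DL1*072	0.12	1
KIR3DL1*073	0.12	1
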