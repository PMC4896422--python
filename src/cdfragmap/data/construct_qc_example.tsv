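# Example construct-triage table for the truncation library of a 355-residue
# uracil-DNA degrading factor: thermofluor melting point (°C), analytical
# gel-filtration elution coordinate, apparent and sequence-derived masses
# (kDa), and the annotated oligomer status.  '-' marks constructs without a
# clear melting transition (CA7, CH9) or without an apparent-mass estimate
# (CA7 elutes in the void as a soluble aggregate).
id	tm	v_el	m_app	m_calc	status
NA1	51.3	62.4	42.1	25.7	dimer
NA2	53.9	56.6	57.0	26.3	dimer
NA3	57.1	69.6	28.9	18.0	dimer
NC6	53.7	55.7	35.6	34.7	monomer
NG1	56.4	60.0	47.7	23.3	dimer
NG3	51.5	64.6	37.5	20.9	dimer
CA7	-	44.3	-	25.4	monomer
CH9	-	58.3	52.1	22.1	dimer
CH10	-	56.0	58.8	32.1	dimer
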