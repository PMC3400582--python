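gene	hsp-4	hsp-6	sod-3	gst-4	function
C06A8.2	1.5	4.5	ns	ns	Transcription; SNAPc
rab-10	1.7	2.6	ns	1.8	RAS GTPase; endocytosis
pas-3	1.8	2.7	2.2	ns	20S proteasome, regulatory subunit
wnk-1	2.0	ns	ns	ns	Serine/threonine protein kinase
cpsf-4	2.3	3.9	ns	ns	mRNA cleavage and polyA specificity
Y50D7A.11	2.5	1.5	ns	ns	Uncharacterized
F18F11.5	2.6	ns	ns	2.4	Serine/threonine protein kinase
mdt-26	3.2	2.8	ns	1.5	Transcription; mediator
F53F4.11	3.6	ns	ns	ns	Uncharacterized
sptl-1	3.6	3.9	ns	2.8	Sphingolipid synthesis
cpsf-2	3.6	27.9	3.0	2.3	mRNA cleavage and polyA specificity
ima-3	3.8	102.6	ns	ns	Importin alpha nuclear transport factor
elt-2	7.5	>>>	3.2	5.8	Transcription factor; intestinal
let-70	9.7	31.6	4.7	2.9	E2 ubiquitin conjugation enzyme
ire-1	13.0	ns	ns	ns	Kinase; ER UPR
ufd-1	ns	1.7	ns	ns	Ubiquitin fusion degradation
cpf-2	ns	2.7	ns	ns	mRNA cleavage and polyA factor
let-92	ns	3.9	3.2	25.1	Serine/threonine protein phosphatase
arf-3	ns	ns	1.5	1.9	ADP-ribosylation factor
dpy-22	ns	ns	1.6	ns	Transcription; mediator
kin-1	ns	ns	2.0	ns	Serine/threonine protein kinase
sdc-2	ns	ns	2.5	ns	Transcriptional repression; dosage comp.
gob-1	ns	ns	3.2	ns	Trehalose synthesis
phi-50	ns	ns	5.8	4.3	Mevalonate synthesis
hda-1	ns	ns	5.9	ns	Histone deacetylase
dcp-66	ns	ns	13.9	ns	Deacetylase; NuRD complex
lin-40	ns	ns	17.2	2.2	Deacetylase; NuRD complex
daf-16	ns	ns	96.3	ns	Transcription factor; insulin/IGF-1 sig.
skr-1	ns	ns	ns	1.5	Ubiquitin ligase complex component
cul-1	ns	ns	ns	1.8	Ubiquitin ligase complex component
skn-1	ns	ns	ns	2.2	Transcription factor; stress, detox
nekl-2	ns	ns	ns	3.3	Serine/threonine protein kinase
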