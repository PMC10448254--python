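# raw name	canonical name
# Cytochrome c oxidase subunits
coi	cox1
coii	cox2
coiii	cox3
co1	cox1
co2	cox2
co3	cox3
cox1	cox1
cox2	cox2
cox3	cox3
coxi	cox1
coxii	cox2
coxiii	cox3
mt-co1	cox1
mt-co2	cox2
mt-co3	cox3
# Cytochrome b
cytb	cob
cyt b	cob
cob	cob
mt-cyb	cob
# NADH dehydrogenase subunits
nd1	nad1
nd2	nad2
nd3	nad3
nd4	nad4
nd4l	nad4l
nd5	nad5
nd6	nad6
nad1	nad1
nad2	nad2
nad3	nad3
nad4	nad4
nad4l	nad4l
nad5	nad5
nad6	nad6
nadh1	nad1
nadh2	nad2
nadh3	nad3
nadh4	nad4
nadh4l	nad4l
nadh5	nad5
nadh6	nad6
# ATP synthase subunits
atp6	atp6
atp8	atp8
atpase6	atp6
atpase8	atp8
atpase 6	atp6
atpase 8	atp8
mt-atp6	atp6
mt-atp8	atp8
# Ribosomal RNAs
12s rrna	rrnS
16s rrna	rrnL
12s	rrnS
16s	rrnL
s-rrna	rrnS
l-rrna	rrnL
rrns	rrnS
rrnl	rrnL
srrn	rrnS
lrrn	rrnL
small subunit ribosomal rna	rrnS
large subunit ribosomal rna	rrnL
# Transfer RNAs (one-letter code form)
trna-ala	trnA
trna-arg	trnR
trna-asn	trnN
trna-asp	trnD
trna-cys	trnC
trna-gln	trnQ
trna-glu	trnE
trna-gly	trnG
trna-his	trnH
trna-ile	trnI
trna-leu	trnL
trna-lys	trnK
trna-met	trnM
trna-phe	trnF
trna-pro	trnP
trna-ser	trnS
trna-thr	trnT
trna-trp	trnW
trna-tyr	trnY
trna-val	trnV
# canonical one-letter tRNA codes (identity)
trna	trnA
trnr	trnR
trnn	trnN
trnd	trnD
trnc	trnC
trnq	trnQ
trne	trnE
trng	trnG
trnh	trnH
trni	trnI
trnk	trnK
trnm	trnM
trnf	trnF
trnp	trnP
trns	trnS
trnt	trnT
trnw	trnW
trny	trnY
trnv	trnV
trnl	trnL
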