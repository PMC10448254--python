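# canonical gene	class
cox1	protein
cox2	protein
cox3	protein
cob	protein
nad1	protein
nad2	protein
nad3	protein
nad4	protein
nad4l	protein
nad5	protein
nad6	protein
atp6	protein
atp8	protein
rrnS	rRNA
rrnL	rRNA
trnA	tRNA
trnR	tRNA
trnN	tRNA
trnD	tRNA
trnC	tRNA
trnQ	tRNA
trnE	tRNA
trnG	tRNA
trnH	tRNA
trnI	tRNA
trnK	tRNA
trnM	tRNA
trnF	tRNA
trnP	tRNA
trnS	tRNA
trnT	tRNA
trnW	tRNA
trnY	tRNA
trnV	tRNA
trnL	tRNA
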