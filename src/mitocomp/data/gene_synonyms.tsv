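# alias	canonical
nad4l	nad4L
ndh4l	nad4L
nd4l	nad4L
nd1	nad1
nd2	nad2
nd3	nad3
nd4	nad4
nd5	nad5
nd6	nad6
rrnl	rnl
rrns	rns
rrn l	rnl
l-rrna	rnl
s-rrna	rns
lsu	rnl
ssu	rns
cytb	cob
cob1	cob
coi	cox1
coii	cox2
coiii	cox3
co1	cox1
co2	cox2
co3	cox3
atpase6	atp6
atpase8	atp8
atpase9	atp9
rps3	rps3
var1	rps3
dpo	dpo
dpob	dpo
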