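index	label
1	Primary optic vesicle
2	Otic placode
3	Allantois bud
4	Torsion complete
5	Secondary optic vesicle
6	Hyomandibular slit
7	Allantois vesicle
8	Choroid fissure open
9	Limb ridge
10	Allantois contacts chorion
11	Maximum pharyngeal slits
12	Limb AER
13	Hemipenal buds
14	Three-segmented limb
15	Jaw initiated
16	Eyelid forms
17	Pharyngeal slits closed
18	Digits differentiated
19	Jaw complete
20	Scale anlagen visible
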