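sample_id	genotype	diet
m01	wt	lin
m02	wt	sun
m03	wt	sun
m04	wt	fish
m05	wt	ref
m06	wt	coc
m07	wt	lin
m08	wt	lin
m09	wt	fish
m10	wt	coc
m11	wt	fish
m12	wt	ref
m13	wt	sun
m14	wt	ref
m15	wt	sun
m16	wt	lin
m17	wt	coc
m18	wt	fish
m19	wt	coc
m20	wt	ref
m21	ppar	coc
m22	ppar	ref
m23	ppar	sun
m24	ppar	fish
m25	ppar	sun
m26	ppar	ref
m27	ppar	ref
m28	ppar	lin
m29	ppar	fish
m30	ppar	lin
m31	ppar	coc
m32	ppar	coc
m33	ppar	ref
m34	ppar	sun
m35	ppar	fish
m36	ppar	coc
m37	ppar	lin
m38	ppar	fish
m39	ppar	lin
m40	ppar	sun
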