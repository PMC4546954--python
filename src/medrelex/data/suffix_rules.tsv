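noun	ss	ss
noun	sses	ss
noun	ies	y
noun	xes	x
noun	zes	z
noun	ches	ch
noun	shes	sh
noun	s
verb	ss	ss
verb	ying	y
verb	ing
verb	ied	y
verb	ed
verb	ies	y
verb	sses	ss
verb	ches	ch
verb	shes	sh
verb	xes	x
verb	zes	z
verb	s
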