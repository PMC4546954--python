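the	DT
a	DT
an	DT
this	DT
that	DT
these	DT
those	DT
each	DT
every	DT
some	DT
any	DT
no	DT
and	CC
or	CC
but	CC
nor	CC
of	IN
in	IN
on	IN
with	IN
for	IN
by	IN
from	IN
at	IN
as	IN
during	IN
after	IN
before	IN
into	IN
between	IN
against	IN
without	IN
among	IN
under	IN
over	IN
to	TO
is	VBZ
are	VBP
was	VBD
were	VBD
be	VB
been	VBN
being	VBG
has	VBZ
have	VBP
had	VBD
do	VBP
does	VBZ
did	VBD
not	RB
may	MD
can	MD
could	MD
will	MD
would	MD
should	MD
must	MD
might	MD
it	PRP
its	PRP$
we	PRP
they	PRP
he	PRP
she	PRP
only	RB
also	RB
very	RB
specifically	RB
one	CD
two	CD
three	CD
four	CD
five	CD
ten	CD
protein	NN
bind	VBP
binds	VBZ
disease	NN
diagnosis	NN
smoking	VBG
causes	VBZ
cause	VB
treats	VBZ
treat	VB
cures	VBZ
cure	VB
prevents	VBZ
prevent	VB
aggravates	VBZ
persists	VBZ
continues	VBZ
correlates	VBZ
affects	VBZ
receives	VBZ
improves	VBZ
reduces	VBZ
induces	VBZ
shows	VBZ
works	VBZ
fails	VBZ
drug	NN
drugs	NNS
patient	NN
patients	NNS
curative	JJ
preventive	JJ
adverse	JJ
chronic	JJ
novel	JJ
possible	JJ
effective	JJ
clinical	JJ
severe	JJ
new	JJ
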