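cure	Cure
cures	Cure
cure/treat for dis.	Cure
cure/treat/dis	Cure
treat_for_dis	Cure
treatment_for_disease	Cure
treatment for disease	Cure
prevent	Prevent
prevents	Prevent
prevent relation	Prevent
prevention	Prevent
sideeffect	SideEffect
side effect	SideEffect
side_effect	SideEffect
side-effect	SideEffect
side_eff	SideEffect
side eff	SideEffect
disonly	DisOnly
dis_only	DisOnly
dis only	DisOnly
disease only	DisOnly
treatonly	TreatOnly
treat_only	TreatOnly
treat only	TreatOnly
treatment only	TreatOnly
vague	Vague
nocure	NoCure
no cure	NoCure
no_cure	NoCure
no cure/treat number for dis.	NoCure
treat_no_for_dis	NoCure
nonrelevant	Nonrelevant
non-relevant	Nonrelevant
non relevant	Nonrelevant
irrelevant	Nonrelevant
to_see	Nonrelevant
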