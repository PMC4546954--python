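achiev
analyz
associat
believ
calculat
caus
combin
compar
comput
continu
creat
cur
decreas
describ
determin
diagnos
divid
dos
enabl
estim
evaluat
examin
generat
giv
improv
includ
increas
indicat
induc
infus
involv
isolat
mak
manag
measur
minimiz
observ
produc
provid
receiv
reduc
relat
releas
remov
requir
sav
smok
stabiliz
stimulat
tak
titrat
translat
us
valu
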