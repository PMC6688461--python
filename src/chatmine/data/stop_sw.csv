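word,language,source
ambao,sw,custom
ambaye,sw,custom
ambayo,sw,custom
asante,sw,custom
au,sw,custom
baada,sw,custom
baadhi,sw,custom
bado,sw,custom
basi,sw,custom
bila,sw,custom
cha,sw,custom
chini,sw,custom
gani,sw,custom
hapa,sw,custom
hapana,sw,custom
hata,sw,custom
haya,sw,custom
hicho,sw,custom
hii,sw,custom
hili,sw,custom
hivyo,sw,custom
hiyo,sw,custom
hizi,sw,custom
huko,sw,custom
huo,sw,custom
huyu,sw,custom
ile,sw,custom
ili,sw,custom
ipi,sw,custom
je,sw,custom
juu,sw,custom
kabla,sw,custom
kama,sw,custom
katika,sw,custom
kila,sw,custom
kile,sw,custom
kuwa,sw,custom
kwa,sw,custom
kwamba,sw,custom
la,sw,custom
lakini,sw,custom
lini,sw,custom
mimi,sw,custom
mpaka,sw,custom
na,sw,custom
nani,sw,custom
naomba,sw,custom
ndani,sw,custom
ndio,sw,custom
ndiyo,sw,custom
ni,sw,custom
nini,sw,custom
ninyi,sw,custom
nje,sw,custom
pale,sw,custom
pia,sw,custom
sana,sw,custom
sasa,sw,custom
si,sw,custom
sisi,sw,custom
tafadhali,sw,custom
tu,sw,custom
ule,sw,custom
vya,sw,custom
wa,sw,custom
wake,sw,custom
wako,sw,custom
wangu,sw,custom
wao,sw,custom
wapi,sw,custom
wewe,sw,custom
ya,sw,custom
yaani,sw,custom
yake,sw,custom
yako,sw,custom
yangu,sw,custom
yeye,sw,custom
yule,sw,custom
za,sw,custom
zile,sw,custom
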