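variant,canonical
menses,period
menstruation,period
monthlies,period
contraceptive,contraception
fp,family planning
coil,iud
loop,iud
preg,pregnant
pregnancy,pregnant
std,sti
stds,sti
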