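inflected,lemma
periods,period
cycles,cycle
pills,pill
condoms,condom
implants,implant
injections,injection
methods,method
effects,effect
infections,infection
diseases,disease
symptoms,symptom
cancers,cancer
days,day
questions,question
answers,answer
relationships,relationship
partners,partner
pregnancies,pregnancy
myths,myth
pains,pain
babies,baby
children,child
women,woman
men,man
girls,girl
boys,boy
clinics,clinic
tests,test
contraceptives,contraceptive
bleeding,bleed
missed,miss
protected,protect
wanted,want
knows,know
helps,help
prevents,prevent
prevented,prevent
preventing,prevent
using,use
used,use
uses,use
taking,take
takes,take
took,take
conceived,conceive
screening,screen
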