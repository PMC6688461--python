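Uzazi wa mpango husaidia watu kuamua lini wapate watoto na wapate watoto wangapi.
Kuna njia nyingi za kisasa za kuzuia mimba, kama vile vidonge, sindano, vipandikizi, kondomu na kitanzi.
Kila njia ina faida zake na madhara yake, na mhudumu wa afya anaweza kukusaidia kuchagua njia bora kwa mwili wako na maisha yako.
Vidonge vya dharura vinaweza kuzuia mimba vikitumiwa mapema baada ya kufanya tendo la ndoa bila kinga.
Kondomu ndiyo njia pekee inayokinga dhidi ya mimba na magonjwa ya zinaa kama vile virusi vya ukimwi.
Kukosa hedhi kunaweza kuwa ishara ya mwanzo ya ujauzito, lakini hedhi inaweza kuchelewa kwa sababu ya msongo wa mawazo, ugonjwa au mabadiliko ya uzito.
Mzunguko wa hedhi ni tofauti kwa kila mwanamke, na mzunguko usio wa kawaida ni jambo la kawaida katika miaka ya mwanzo.
Ukiwa na damu nyingi, maumivu makali au kutokwa na damu kati ya hedhi, ni vizuri kwenda kliniki.
Vijana wengi wanataka kujua kuhusu siku salama, lakini kuhesabu siku ni mojawapo ya njia zisizo za uhakika za kuzuia mimba.
Uchunguzi wa saratani ya matiti na saratani ya shingo ya kizazi unaweza kugundua tatizo mapema, wakati matibabu yanafanya kazi vizuri.
Kupima virusi vya ukimwi ni haraka na ni siri, na kujua hali yako kunakusaidia kujilinda wewe na mpenzi wako.
Watu wengine wanahofia kwamba njia za uzazi wa mpango husababisha ugumba, lakini uwezo wa kuzaa hurudi mara nyingi baada ya kuacha kutumia njia.
Kipandikizi ni kijiti kidogo kinachowekwa chini ya ngozi ya mkono na kinazuia mimba kwa miaka kadhaa.
Sindano hutolewa kila baada ya miezi mitatu na ni ya siri, kwa sababu hakuna mtu anayeweza kuona kwamba unaitumia.
Vidonge lazima vinywewe kila siku kwa wakati uleule ili vifanye kazi vizuri.
Baada ya kujifungua, kunyonyesha kunaweza kuchelewesha kurudi kwa uwezo wa kuzaa, lakini si njia ya uhakika peke yake.
Maumivu wakati wa tendo la ndoa, uchafu usio wa kawaida au vidonda vinaweza kuwa ishara ya maambukizi yanayohitaji matibabu.
Ni jambo la kawaida kuwa na maswali kuhusu mwili wako, mahusiano na afya ya uzazi, na kuuliza maswali ni hatua ya kwanza ya kuwa na afya njema.
Huduma za afya zinapatikana katika zahanati za umma, na huduma nyingi kwa vijana ni za bure au za gharama nafuu.
Kuzungumza waziwazi na mpenzi wako kuhusu uzazi wa mpango na kupima kunajenga uaminifu na kunawaweka salama nyote wawili.
Pombe na matumizi ya dawa za kulevya yanaweza kusababisha maamuzi ambayo watu hujutia baadaye.
Ukidhani una ujauzito, kipimo cha mimba katika kliniki au duka la dawa kinaweza kukupa jibu haraka.
Hakuna swali kuhusu afya yako ambalo ni dogo sana au la aibu sana kuuliza.
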