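Family planning helps people decide when to have children and how many children to have.
There are many modern methods of contraception, including pills, injections, implants, condoms and intrauterine devices.
Every method has advantages and possible side effects, and a health worker can help you choose the best method for your body and your life.
Emergency contraception can prevent pregnancy if it is taken soon after unprotected sex.
Condoms are the only method that protects against both pregnancy and sexually transmitted infections such as HIV.
A missed period can be an early sign of pregnancy, but periods can also be late because of stress, illness or changes in weight.
Menstrual cycles are different for every woman, and an irregular cycle is common in the first years after periods begin.
If you have heavy bleeding, severe pain or bleeding between periods, it is a good idea to visit a clinic.
Many young people want to know about safe days, but counting days is one of the least reliable ways to prevent pregnancy.
Breast cancer and cervical cancer screening can find problems early, when treatment works best.
Testing for HIV is quick and confidential, and knowing your status helps you protect yourself and your partner.
Some people worry that contraception causes infertility, but fertility usually returns soon after stopping most methods.
An implant is a small rod placed under the skin of the arm that prevents pregnancy for several years.
The injection is given every three months and is private, because nobody can see that you are using it.
Pills must be taken every day at the same time to work well.
After giving birth, breastfeeding can delay the return of fertility, but it is not a reliable method on its own.
Pain during sex, unusual discharge or sores can be signs of an infection that needs treatment.
It is normal to have questions about your body, relationships and sexual health, and asking questions is the first step to staying healthy.
Health services are available at public clinics, and many services for young people are free or low cost.
Talking openly with your partner about contraception and testing builds trust and keeps both of you safe.
Alcohol and drug use can lead to decisions that people later regret, including unprotected sex.
If you think you might be pregnant, a pregnancy test at a clinic or from a pharmacy can give you an answer quickly.
No question about your health is too small or too embarrassing to ask.
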