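a
abortion
about
abstinence
advantages
advice
after
against
aids
alcohol
also
an
and
answer
answers
are
arm
as
ask
asking
at
available
babies
baby
be
because
begin
best
between
birth
bleeding
body
both
boy
boyfriend
boys
breast
breastfeeding
builds
but
can
cancer
cancers
causes
cervical
cervix
changes
child
children
choose
clinic
clinics
coil
common
conceive
conception
condom
condoms
confidential
contraception
contraceptive
contraceptives
control
cost
counting
cycle
cycles
day
days
decide
decisions
delay
devices
different
discharge
disease
diseases
doctor
drug
during
early
effect
effective
effectiveness
effects
embarrassing
emergency
every
family
fertile
fertility
find
first
for
free
from
girl
girlfriend
girls
give
given
giving
good
has
have
health
healthy
heavy
help
helps
hiv
hospital
how
husband
idea
if
illness
implant
implants
in
including
infection
infections
infertility
information
injection
injections
intrauterine
irregular
is
it
its
keeps
know
knowing
late
later
lead
least
life
loop
low
man
many
men
menses
menstrual
menstruation
method
methods
might
missed
modern
months
morning
most
must
myth
myths
need
needs
no
nobody
normal
not
nurse
of
on
one
only
openly
or
ovulation
own
pain
painful
pains
partner
partners
people
period
periods
pharmacy
pill
pills
placed
planning
possible
pregnancies
pregnancy
pregnant
prevent
prevention
prevents
private
problems
prostate
protect
protected
protection
protects
public
question
questions
quick
quickly
regret
relationship
relationships
reliable
return
returns
rod
safe
same
screen
screening
see
services
several
severe
sex
sexual
sexually
side
sign
signs
skin
small
some
soon
sores
status
staying
step
sti
stopping
stress
such
symptom
symptoms
taken
talking
test
testing
tests
that
the
there
think
three
time
to
too
transmitted
treatment
trust
under
unprotected
unsafe
unusual
use
using
usually
uti
virgin
virginity
visit
want
ways
weight
well
when
wife
with
withdrawal
woman
women
work
worker
works
worry
years
you
young
your
yourself
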