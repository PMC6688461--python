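word,language,source
a,en,sklearn
about,en,sklearn
above,en,sklearn
across,en,sklearn
after,en,sklearn
afterwards,en,sklearn
again,en,sklearn
against,en,sklearn
all,en,sklearn
almost,en,sklearn
alone,en,sklearn
along,en,sklearn
already,en,sklearn
also,en,sklearn
although,en,sklearn
always,en,sklearn
am,en,sklearn
among,en,sklearn
amongst,en,sklearn
amoungst,en,sklearn
amount,en,sklearn
an,en,sklearn
and,en,sklearn
another,en,sklearn
any,en,sklearn
anyhow,en,sklearn
anyone,en,sklearn
anything,en,sklearn
anyway,en,sklearn
anywhere,en,sklearn
are,en,sklearn
around,en,sklearn
as,en,sklearn
at,en,sklearn
back,en,sklearn
be,en,sklearn
became,en,sklearn
because,en,sklearn
become,en,sklearn
becomes,en,sklearn
becoming,en,sklearn
been,en,sklearn
before,en,sklearn
beforehand,en,sklearn
behind,en,sklearn
being,en,sklearn
below,en,sklearn
beside,en,sklearn
besides,en,sklearn
between,en,sklearn
beyond,en,sklearn
bill,en,sklearn
both,en,sklearn
bottom,en,sklearn
but,en,sklearn
by,en,sklearn
call,en,sklearn
can,en,sklearn
cannot,en,sklearn
cant,en,sklearn
co,en,sklearn
con,en,sklearn
could,en,sklearn
couldnt,en,sklearn
cry,en,sklearn
de,en,sklearn
describe,en,sklearn
detail,en,sklearn
do,en,sklearn
done,en,sklearn
down,en,sklearn
due,en,sklearn
during,en,sklearn
each,en,sklearn
eg,en,sklearn
eight,en,sklearn
either,en,sklearn
eleven,en,sklearn
else,en,sklearn
elsewhere,en,sklearn
empty,en,sklearn
enough,en,sklearn
etc,en,sklearn
even,en,sklearn
ever,en,sklearn
every,en,sklearn
everyone,en,sklearn
everything,en,sklearn
everywhere,en,sklearn
except,en,sklearn
few,en,sklearn
fifteen,en,sklearn
fifty,en,sklearn
fill,en,sklearn
find,en,sklearn
fire,en,sklearn
first,en,sklearn
five,en,sklearn
for,en,sklearn
former,en,sklearn
formerly,en,sklearn
forty,en,sklearn
found,en,sklearn
four,en,sklearn
from,en,sklearn
front,en,sklearn
full,en,sklearn
further,en,sklearn
get,en,sklearn
give,en,sklearn
go,en,sklearn
had,en,sklearn
has,en,sklearn
hasnt,en,sklearn
have,en,sklearn
he,en,sklearn
hence,en,sklearn
her,en,sklearn
here,en,sklearn
hereafter,en,sklearn
hereby,en,sklearn
herein,en,sklearn
hereupon,en,sklearn
hers,en,sklearn
herself,en,sklearn
him,en,sklearn
himself,en,sklearn
his,en,sklearn
how,en,sklearn
however,en,sklearn
hundred,en,sklearn
i,en,sklearn
ie,en,sklearn
if,en,sklearn
in,en,sklearn
inc,en,sklearn
indeed,en,sklearn
interest,en,sklearn
into,en,sklearn
is,en,sklearn
it,en,sklearn
its,en,sklearn
itself,en,sklearn
keep,en,sklearn
last,en,sklearn
latter,en,sklearn
latterly,en,sklearn
least,en,sklearn
less,en,sklearn
ltd,en,sklearn
made,en,sklearn
many,en,sklearn
may,en,sklearn
me,en,sklearn
meanwhile,en,sklearn
might,en,sklearn
mill,en,sklearn
mine,en,sklearn
more,en,sklearn
moreover,en,sklearn
most,en,sklearn
mostly,en,sklearn
move,en,sklearn
much,en,sklearn
must,en,sklearn
my,en,sklearn
myself,en,sklearn
name,en,sklearn
namely,en,sklearn
neither,en,sklearn
never,en,sklearn
nevertheless,en,sklearn
next,en,sklearn
nine,en,sklearn
no,en,sklearn
nobody,en,sklearn
none,en,sklearn
noone,en,sklearn
nor,en,sklearn
not,en,sklearn
nothing,en,sklearn
now,en,sklearn
nowhere,en,sklearn
of,en,sklearn
off,en,sklearn
often,en,sklearn
on,en,sklearn
once,en,sklearn
one,en,sklearn
only,en,sklearn
onto,en,sklearn
or,en,sklearn
other,en,sklearn
others,en,sklearn
otherwise,en,sklearn
our,en,sklearn
ours,en,sklearn
ourselves,en,sklearn
out,en,sklearn
over,en,sklearn
own,en,sklearn
part,en,sklearn
per,en,sklearn
perhaps,en,sklearn
please,en,sklearn
put,en,sklearn
rather,en,sklearn
re,en,sklearn
same,en,sklearn
see,en,sklearn
seem,en,sklearn
seemed,en,sklearn
seeming,en,sklearn
seems,en,sklearn
serious,en,sklearn
several,en,sklearn
she,en,sklearn
should,en,sklearn
show,en,sklearn
side,en,sklearn
since,en,sklearn
sincere,en,sklearn
six,en,sklearn
sixty,en,sklearn
so,en,sklearn
some,en,sklearn
somehow,en,sklearn
someone,en,sklearn
something,en,sklearn
sometime,en,sklearn
sometimes,en,sklearn
somewhere,en,sklearn
still,en,sklearn
such,en,sklearn
system,en,sklearn
take,en,sklearn
ten,en,sklearn
than,en,sklearn
that,en,sklearn
the,en,sklearn
their,en,sklearn
them,en,sklearn
themselves,en,sklearn
then,en,sklearn
thence,en,sklearn
there,en,sklearn
thereafter,en,sklearn
thereby,en,sklearn
therefore,en,sklearn
therein,en,sklearn
thereupon,en,sklearn
these,en,sklearn
they,en,sklearn
thick,en,sklearn
thin,en,sklearn
third,en,sklearn
this,en,sklearn
those,en,sklearn
though,en,sklearn
three,en,sklearn
through,en,sklearn
throughout,en,sklearn
thru,en,sklearn
thus,en,sklearn
to,en,sklearn
together,en,sklearn
too,en,sklearn
top,en,sklearn
toward,en,sklearn
towards,en,sklearn
twelve,en,sklearn
twenty,en,sklearn
two,en,sklearn
un,en,sklearn
under,en,sklearn
until,en,sklearn
up,en,sklearn
upon,en,sklearn
us,en,sklearn
very,en,sklearn
via,en,sklearn
was,en,sklearn
we,en,sklearn
well,en,sklearn
were,en,sklearn
what,en,sklearn
whatever,en,sklearn
when,en,sklearn
whence,en,sklearn
whenever,en,sklearn
where,en,sklearn
whereafter,en,sklearn
whereas,en,sklearn
whereby,en,sklearn
wherein,en,sklearn
whereupon,en,sklearn
wherever,en,sklearn
whether,en,sklearn
which,en,sklearn
while,en,sklearn
whither,en,sklearn
who,en,sklearn
whoever,en,sklearn
whole,en,sklearn
whom,en,sklearn
whose,en,sklearn
why,en,sklearn
will,en,sklearn
with,en,sklearn
within,en,sklearn
without,en,sklearn
would,en,sklearn
yet,en,sklearn
you,en,sklearn
your,en,sklearn
yours,en,sklearn
yourself,en,sklearn
yourselves,en,sklearn
asante,en,custom
cos,en,custom
coz,en,custom
dat,en,custom
didnt,en,custom
dont,en,custom
hello,en,custom
hey,en,custom
hi,en,custom
im,en,custom
na,en,custom
ok,en,custom
okay,en,custom
pls,en,custom
sawa,en,custom
thank,en,custom
thanks,en,custom
u,en,custom
ur,en,custom
wat,en,custom
wats,en,custom
whats,en,custom
yeah,en,custom
yes,en,custom
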