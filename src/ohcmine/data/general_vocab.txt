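a
about
above
after
again
against
ago
alcohol
all
almost
alone
along
already
also
although
always
among
and
another
answer
any
anymore
anyone
anything
appointment
around
as
ask
asked
at
autumn
away
back
bad
be
became
because
become
been
before
began
behind
being
believe
best
better
between
big
both
brand
bring
brother
brought
but
by
call
called
came
can
cannot
capsule
care
carry
case
change
children
clinic
come
common
condition
could
countries
country
course
cut
daily
day
days
did
different
do
doctor
doctors
does
done
dosage
dose
doses
down
drug
drugs
during
each
early
effect
effects
end
enough
even
evening
ever
every
everything
experience
face
fact
family
far
father
feel
feeling
feels
feet
felt
few
find
first
follow
food
for
form
found
four
friend
from
full
gave
generic
get
girl
give
given
go
goes
going
gone
good
got
grapefruit
great
group
grow
had
hand
hard
has
have
he
head
hear
heard
held
help
helped
helping
helps
her
here
high
him
himself
his
home
hope
hospital
hour
house
how
however
husband
i
idea
if
important
in
insurance
interact
into
is
it
its
juice
just
keep
kept
kind
knew
know
known
large
last
late
later
learn
leave
left
less
let
letter
life
light
like
line
little
live
local
long
look
looked
lot
made
make
man
many
may
mean
medication
medications
medicine
men
might
mind
miss
month
months
more
morning
most
mother
move
much
must
my
name
near
need
never
new
next
night
no
not
nothing
now
number
nurse
of
off
often
old
on
once
one
only
open
or
order
other
our
out
over
own
part
people
perhaps
pharmacist
pharmacy
pill
pills
place
point
prescribe
prescribed
prescription
put
question
quite
rather
read
real
really
reason
refill
relief
relieve
rest
right
room
said
same
saw
say
school
second
see
seem
seen
sentence
set
several
shall
she
should
show
side
since
sister
small
so
some
someone
something
sometimes
soon
sound
spring
start
started
starting
state
still
stop
stopped
stopping
story
study
such
suggested
summer
sure
symptom
symptoms
tablet
tablets
take
taken
takes
taking
tell
than
that
the
their
them
then
therapy
there
these
they
thing
think
this
those
though
thought
three
through
time
to
today
together
told
too
took
toward
treat
treated
treatment
tried
try
trying
turn
twice
two
unclear
under
until
up
upon
us
use
used
usual
very
visit
want
was
water
way
we
week
weeks
well
went
were
what
when
where
which
while
white
who
whole
why
wife
will
winter
with
within
without
word
work
worked
working
works
world
worse
would
write
year
years
yet
you
young
your
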