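# Common English words erroneously tagged as names by loose recognizers.
# Scrub vocabulary; lower-case, one per line.
about
after
again
all
also
always
and
any
appointment
are
assist
assistance
available
bath
bathing
because
bed
been
before
being
best
both
but
call
called
calls
came
can
cannot
care
cares
chart
clinic
come
comes
concern
concerns
contact
contacted
could
daily
day
days
discussed
doctor
does
done
dressing
drive
drives
driving
due
during
each
eating
every
faith
family
feeding
feels
follow
for
from
get
gets
give
given
goes
good
grace
had
has
have
health
help
helped
helps
her
here
him
his
home
hope
hospital
house
how
its
joy
just
last
left
like
lives
living
long
made
makes
many
may
medication
medications
meds
meeting
member
message
more
morning
most
much
must
near
need
needs
new
next
night
not
notes
noted
now
office
often
once
only
other
our
out
over
patient
per
phone
place
plan
please
present
primary
problem
provide
provides
questions
regarding
reports
requests
review
ride
rides
room
said
same
says
see
seen
sent
she
should
since
some
soon
staff
state
states
stated
stay
stays
still
such
support
take
takes
than
thank
thanks
that
the
their
them
then
there
they
this
time
times
today
told
tomorrow
took
update
updated
very
visit
visits
voicemail
was
week
weekly
well
went
were
what
when
where
which
while
who
will
with
would
yes
yesterday
your
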