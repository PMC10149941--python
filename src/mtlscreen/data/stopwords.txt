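# Frozen English stopword list. Personal pronouns (first/second/third person,
# subject/object/possessive/reflexive) are deliberately absent: they are kept
# in the text because first-person-singular usage is itself a depression
# signal. Lines starting with '#' are ignored.
a
about
above
after
again
against
all
am
an
and
any
are
aren
as
at
be
because
been
before
being
below
between
both
but
by
can
couldn
d
did
didn
do
does
doesn
doing
don
down
during
each
few
for
from
further
had
hadn
has
hasn
have
haven
having
here
how
if
in
into
is
isn
just
ll
m
ma
mightn
more
most
mustn
needn
no
nor
not
now
o
of
off
on
once
only
or
other
out
over
own
re
s
same
shan
should
shouldn
so
some
such
t
than
that
the
then
there
these
this
those
through
to
too
under
until
up
ve
very
was
wasn
were
weren
what
when
where
which
while
who
whom
why
will
with
won
wouldn
y
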