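# Default English stopword list used for GO-label token cleaning.
# One word per line; lines starting with '#' are ignored.
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
cannot
could
did
do
does
doing
down
during
each
few
for
from
further
had
has
have
having
he
her
here
hers
him
his
how
i
if
in
into
is
it
its
itself
me
more
most
my
no
nor
not
of
off
on
once
only
or
other
ought
our
ours
out
over
own
same
she
should
so
some
such
than
that
the
their
theirs
them
then
there
these
they
this
those
through
to
too
under
until
up
very
via
was
we
were
what
when
where
which
while
who
whom
why
with
would
you
your
yours
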