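# Versioned stopword list for title-keyword extraction.
# Function words only; content-bearing words are never listed here,
# since dropping one would silently change the keyword vocabulary K.
a
about
above
across
after
against
along
amid
among
an
and
are
as
at
based
be
because
been
before
being
below
between
beyond
both
but
by
can
could
did
do
does
during
each
for
from
further
had
has
have
having
how
if
in
into
is
it
its
may
might
more
most
no
nor
not
of
off
on
onto
or
other
our
over
per
should
since
so
some
such
than
that
the
their
them
then
there
these
they
this
those
through
to
toward
towards
under
until
up
upon
use
using
versus
via
vs
was
were
what
when
where
whether
which
while
who
whose
why
will
with
within
without
would
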